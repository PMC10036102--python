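energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,1.1628e+02,1.1519e+02,1.1519e+02,9.9074e-02,9.9270e-01
5.2867e+00,9.8910e+01,9.7865e+01,9.7864e+01,1.0336e-01,9.4296e-01
5.5899e+00,8.4101e+01,8.3101e+01,8.3100e+01,1.0764e-01,8.9319e-01
5.9104e+00,7.1482e+01,7.0528e+01,7.0527e+01,1.1187e-01,8.4372e-01
6.2493e+00,6.0736e+01,5.9827e+01,5.9825e+01,1.1602e-01,7.9486e-01
6.6076e+00,5.1588e+01,5.0723e+01,5.0721e+01,1.2008e-01,7.4692e-01
6.9865e+00,4.3805e+01,4.2983e+01,4.2981e+01,1.2401e-01,7.0018e-01
7.3871e+00,3.7186e+01,3.6405e+01,3.6403e+01,1.2780e-01,6.5488e-01
7.8107e+00,3.1558e+01,3.0818e+01,3.0816e+01,1.3142e-01,6.1123e-01
8.2586e+00,2.6777e+01,2.6075e+01,2.6073e+01,1.3485e-01,5.6939e-01
8.7321e+00,2.2716e+01,2.2051e+01,2.2048e+01,1.3810e-01,5.2949e-01
9.2329e+00,1.9254e+01,1.8623e+01,1.8621e+01,1.4115e-01,4.9162e-01
9.7623e+00,1.6313e+01,1.5716e+01,1.5714e+01,1.4399e-01,4.5581e-01
1.0322e+01,1.3824e+01,1.3258e+01,1.3255e+01,1.4663e-01,4.2209e-01
1.0914e+01,1.1717e+01,1.1180e+01,1.1177e+01,1.4906e-01,3.9045e-01
1.1540e+01,9.9336e+00,9.4247e+00,9.4215e+00,1.5129e-01,3.6085e-01
1.2201e+01,8.4251e+00,7.9420e+00,7.9385e+00,1.5332e-01,3.3324e-01
1.2901e+01,7.1492e+00,6.6902e+00,6.6865e+00,1.5515e-01,3.0755e-01
1.3641e+01,6.0703e+00,5.6337e+00,5.6298e+00,1.5680e-01,2.8369e-01
1.4423e+01,5.1581e+00,4.7425e+00,4.7383e+00,1.5827e-01,2.6157e-01
1.5250e+01,4.3871e+00,3.9909e+00,3.9865e+00,1.5958e-01,2.4108e-01
1.6125e+01,3.7355e+00,3.3574e+00,3.3526e+00,1.6071e-01,2.2211e-01
1.7049e+01,3.1848e+00,2.8236e+00,2.8185e+00,1.6170e-01,2.0456e-01
1.8027e+01,2.7195e+00,2.3740e+00,2.3686e+00,1.6254e-01,1.8832e-01
1.9060e+01,2.3263e+00,1.9954e+00,1.9898e+00,1.6324e-01,1.7329e-01
2.0153e+01,1.9941e+00,1.6768e+00,1.6709e+00,1.6381e-01,1.5938e-01
2.1309e+01,1.7133e+00,1.4089e+00,1.4026e+00,1.6426e-01,1.4650e-01
2.2531e+01,1.4761e+00,1.1835e+00,1.1769e+00,1.6458e-01,1.3458e-01
2.3823e+01,1.2755e+00,9.9408e-01,9.8711e-01,1.6480e-01,1.2356e-01
2.5189e+01,1.1059e+00,8.3498e-01,8.2764e-01,1.6490e-01,1.1336e-01
2.6633e+01,9.6254e-01,7.0146e-01,6.9374e-01,1.6490e-01,1.0390e-01
2.8160e+01,8.4125e-01,5.8945e-01,5.8134e-01,1.6480e-01,9.5101e-02
2.9775e+01,7.3856e-01,4.9552e-01,4.8701e-01,1.6461e-01,8.6942e-02
3.1482e+01,6.5157e-01,4.1678e-01,4.0785e-01,1.6433e-01,7.9388e-02
3.3288e+01,5.7781e-01,3.5081e-01,3.4146e-01,1.6395e-01,7.2405e-02
3.5196e+01,5.1523e-01,2.9558e-01,2.8579e-01,1.6348e-01,6.5961e-02
3.7215e+01,4.6207e-01,2.4936e-01,2.3912e-01,1.6293e-01,6.0025e-02
3.9349e+01,4.1686e-01,2.1071e-01,2.0001e-01,1.6229e-01,5.4567e-02
4.1605e+01,3.7837e-01,1.7842e-01,1.6724e-01,1.6157e-01,4.9557e-02
4.3991e+01,3.4554e-01,1.5146e-01,1.3980e-01,1.6077e-01,4.4966e-02
4.6513e+01,3.1748e-01,1.2898e-01,1.1683e-01,1.5989e-01,4.0767e-02
4.9180e+01,2.9346e-01,1.1025e-01,9.7601e-02,1.5893e-01,3.6931e-02
5.2000e+01,2.7285e-01,9.4675e-02,8.1512e-02,1.5790e-01,3.3432e-02
5.4982e+01,2.5510e-01,8.1736e-02,6.8055e-02,1.5680e-01,3.0245e-02
5.8135e+01,2.3978e-01,7.1007e-02,5.6801e-02,1.5563e-01,2.7346e-02
6.1468e+01,2.2650e-01,6.2131e-02,4.7394e-02,1.5439e-01,2.4710e-02
6.4993e+01,2.1494e-01,5.4806e-02,3.9532e-02,1.5309e-01,2.2317e-02
6.8719e+01,2.0484e-01,4.8779e-02,3.2965e-02,1.5172e-01,2.0146e-02
7.2660e+01,1.9596e-01,4.3838e-02,2.7480e-02,1.5030e-01,1.8177e-02
7.6826e+01,1.8811e-01,3.9804e-02,2.2900e-02,1.4882e-01,1.6393e-02
8.1232e+01,1.8113e-01,3.6528e-02,1.9078e-02,1.4728e-01,1.4777e-02
8.5890e+01,1.7489e-01,3.3885e-02,1.5889e-02,1.4569e-01,1.3315e-02
9.0815e+01,1.6926e-01,3.1768e-02,1.3229e-02,1.4404e-01,1.1992e-02
9.6022e+01,1.6416e-01,3.0091e-02,1.1011e-02,1.4235e-01,1.0796e-02
1.0153e+02,1.5949e-01,2.8778e-02,9.1614e-03,1.4062e-01,9.7153e-03
1.0735e+02,1.5520e-01,2.7768e-02,7.6205e-03,1.3884e-01,8.7391e-03
1.1351e+02,1.5121e-01,2.7007e-02,6.3368e-03,1.3702e-01,7.8579e-03
1.2001e+02,1.4749e-01,2.6453e-02,5.2677e-03,1.3516e-01,7.0629e-03
1.2690e+02,1.4399e-01,2.6068e-02,4.3776e-03,1.3327e-01,6.3460e-03
1.3417e+02,1.4068e-01,2.5821e-02,3.6368e-03,1.3134e-01,5.6998e-03
1.4187e+02,1.3753e-01,2.5686e-02,3.0204e-03,1.2939e-01,5.1178e-03
1.5000e+02,1.3451e-01,2.5641e-02,2.5077e-03,1.2741e-01,4.5937e-03
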