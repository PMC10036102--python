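energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,3.0054e+01,2.9449e+01,2.9448e+01,1.2896e-01,4.7747e-01
5.2867e+00,2.5398e+01,2.4819e+01,2.4818e+01,1.3302e-01,4.4726e-01
5.5899e+00,2.1461e+01,2.0907e+01,2.0906e+01,1.3688e-01,4.1846e-01
5.9104e+00,1.8133e+01,1.7603e+01,1.7602e+01,1.4052e-01,3.9114e-01
6.2493e+00,1.5321e+01,1.4814e+01,1.4812e+01,1.4393e-01,3.6530e-01
6.6076e+00,1.2947e+01,1.2461e+01,1.2459e+01,1.4712e-01,3.4095e-01
6.9865e+00,1.0942e+01,1.0476e+01,1.0474e+01,1.5008e-01,3.1809e-01
7.3871e+00,9.2505e+00,8.8032e+00,8.8010e+00,1.5282e-01,2.9667e-01
7.8107e+00,7.8230e+00,7.3933e+00,7.3910e+00,1.5535e-01,2.7667e-01
8.2586e+00,6.6197e+00,6.2065e+00,6.2041e+00,1.5768e-01,2.5800e-01
8.7321e+00,5.6062e+00,5.2084e+00,5.2058e+00,1.5981e-01,2.4060e-01
9.2329e+00,4.7484e+00,4.3651e+00,4.3622e+00,1.6175e-01,2.2439e-01
9.7623e+00,4.0255e+00,3.6557e+00,3.6527e+00,1.6352e-01,2.0927e-01
1.0322e+01,3.4182e+00,3.0611e+00,3.0579e+00,1.6513e-01,1.9515e-01
1.0914e+01,2.9080e+00,2.5628e+00,2.5594e+00,1.6659e-01,1.8195e-01
1.1540e+01,2.4792e+00,2.1454e+00,2.1418e+00,1.6791e-01,1.6958e-01
1.2201e+01,2.1189e+00,1.7957e+00,1.7918e+00,1.6910e-01,1.5797e-01
1.2901e+01,1.8160e+00,1.5029e+00,1.4988e+00,1.7016e-01,1.4706e-01
1.3641e+01,1.5613e+00,1.2577e+00,1.2534e+00,1.7111e-01,1.3678e-01
1.4423e+01,1.3470e+00,1.0525e+00,1.0479e+00,1.7195e-01,1.2709e-01
1.5250e+01,1.1666e+00,8.8081e-01,8.7597e-01,1.7268e-01,1.1795e-01
1.6125e+01,1.0147e+00,7.3719e-01,7.3208e-01,1.7331e-01,1.0933e-01
1.7049e+01,8.8672e-01,6.1709e-01,6.1169e-01,1.7384e-01,1.0119e-01
1.8027e+01,7.7878e-01,5.1669e-01,5.1099e-01,1.7428e-01,9.3522e-02
1.9060e+01,6.8768e-01,4.3279e-01,4.2677e-01,1.7461e-01,8.6296e-02
2.0153e+01,6.1072e-01,3.6271e-01,3.5636e-01,1.7486e-01,7.9499e-02
2.1309e+01,5.4563e-01,3.0419e-01,2.9750e-01,1.7501e-01,7.3115e-02
2.2531e+01,4.9051e-01,2.5535e-01,2.4831e-01,1.7507e-01,6.7132e-02
2.3823e+01,4.4379e-01,2.1462e-01,2.0721e-01,1.7504e-01,6.1535e-02
2.5189e+01,4.0411e-01,1.8066e-01,1.7288e-01,1.7492e-01,5.6312e-02
2.6633e+01,3.7036e-01,1.5238e-01,1.4420e-01,1.7471e-01,5.1456e-02
2.8160e+01,3.4142e-01,1.2863e-01,1.2006e-01,1.7441e-01,4.6956e-02
2.9775e+01,3.1676e-01,1.0894e-01,9.9941e-02,1.7402e-01,4.2800e-02
3.1482e+01,2.9572e-01,9.2621e-02,8.3195e-02,1.7355e-01,3.8969e-02
3.3288e+01,2.7769e-01,7.9121e-02,6.9253e-02,1.7300e-01,3.5446e-02
3.5196e+01,2.6222e-01,6.7968e-02,5.7646e-02,1.7236e-01,3.2212e-02
3.7215e+01,2.4887e-01,5.8771e-02,4.7983e-02,1.7164e-01,2.9250e-02
3.9349e+01,2.3732e-01,5.1205e-02,3.9939e-02,1.7084e-01,2.6539e-02
4.1605e+01,2.2727e-01,4.4998e-02,3.3242e-02,1.6997e-01,2.4062e-02
4.3991e+01,2.1849e-01,3.9924e-02,2.7668e-02,1.6902e-01,2.1802e-02
4.6513e+01,2.1077e-01,3.5795e-02,2.3027e-02,1.6800e-01,1.9740e-02
4.9180e+01,2.0394e-01,3.2452e-02,1.9165e-02,1.6691e-01,1.7862e-02
5.2000e+01,1.9785e-01,2.9767e-02,1.5949e-02,1.6575e-01,1.6152e-02
5.4982e+01,1.9239e-01,2.7628e-02,1.3273e-02,1.6453e-01,1.4596e-02
5.8135e+01,1.8746e-01,2.5946e-02,1.1046e-02,1.6323e-01,1.3182e-02
6.1468e+01,1.8297e-01,2.4644e-02,9.1920e-03,1.6188e-01,1.1898e-02
6.4993e+01,1.7884e-01,2.3658e-02,7.6490e-03,1.6046e-01,1.0733e-02
6.8719e+01,1.7502e-01,2.2936e-02,6.3649e-03,1.5898e-01,9.6760e-03
7.2660e+01,1.7146e-01,2.2432e-02,5.2962e-03,1.5745e-01,8.7183e-03
7.6826e+01,1.6811e-01,2.2110e-02,4.4068e-03,1.5585e-01,7.8511e-03
8.1232e+01,1.6494e-01,2.1938e-02,3.6666e-03,1.5421e-01,7.0665e-03
8.5890e+01,1.6192e-01,2.1889e-02,3.0507e-03,1.5251e-01,6.3572e-03
9.0815e+01,1.5902e-01,2.1942e-02,2.5382e-03,1.5076e-01,5.7164e-03
9.6022e+01,1.5622e-01,2.2078e-02,2.1117e-03,1.4897e-01,5.1380e-03
1.0153e+02,1.5350e-01,2.2282e-02,1.7568e-03,1.4713e-01,4.6161e-03
1.0735e+02,1.5085e-01,2.2538e-02,1.4616e-03,1.4524e-01,4.1457e-03
1.1351e+02,1.4826e-01,2.2837e-02,1.2159e-03,1.4332e-01,3.7218e-03
1.2001e+02,1.4571e-01,2.3168e-02,1.0115e-03,1.4136e-01,3.3402e-03
1.2690e+02,1.4320e-01,2.3524e-02,8.4139e-04,1.3937e-01,2.9967e-03
1.3417e+02,1.4073e-01,2.3896e-02,6.9989e-04,1.3734e-01,2.6879e-03
1.4187e+02,1.3828e-01,2.4280e-02,5.8217e-04,1.3528e-01,2.4102e-03
1.5000e+02,1.3585e-01,2.4669e-02,4.8424e-04,1.3320e-01,2.1607e-03
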