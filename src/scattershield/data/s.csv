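energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,3.4594e+02,3.4447e+02,3.4447e+02,1.1269e-01,1.3533e+00
5.2867e+00,2.9685e+02,2.9544e+02,2.9544e+02,1.1606e-01,1.2960e+00
5.5899e+00,2.5456e+02,2.5320e+02,2.5320e+02,1.1932e-01,1.2403e+00
5.9104e+00,2.1816e+02,2.1686e+02,2.1685e+02,1.2248e-01,1.1860e+00
6.2493e+00,1.8685e+02,1.8559e+02,1.8559e+02,1.2553e-01,1.1331e+00
6.6076e+00,1.5993e+02,1.5873e+02,1.5872e+02,1.2850e-01,1.0814e+00
6.9865e+00,1.3681e+02,1.3565e+02,1.3565e+02,1.3139e-01,1.0307e+00
7.3871e+00,1.1696e+02,1.1585e+02,1.1585e+02,1.3420e-01,9.8084e-01
7.8107e+00,9.9932e+01,9.8865e+01,9.8863e+01,1.3695e-01,9.3172e-01
8.2586e+00,8.5332e+01,8.4311e+01,8.4309e+01,1.3964e-01,8.8330e-01
8.7321e+00,7.2824e+01,7.1849e+01,7.1846e+01,1.4226e-01,8.3557e-01
9.2329e+00,6.2100e+01,6.1169e+01,6.1166e+01,1.4481e-01,7.8857e-01
9.7623e+00,5.2927e+01,5.2040e+01,5.2037e+01,1.4729e-01,7.4240e-01
1.0322e+01,4.5093e+01,4.4249e+01,4.4246e+01,1.4968e-01,6.9716e-01
1.0914e+01,3.8394e+01,3.7592e+01,3.7589e+01,1.5198e-01,6.5302e-01
1.1540e+01,3.2664e+01,3.1903e+01,3.1900e+01,1.5418e-01,6.1013e-01
1.2201e+01,2.7784e+01,2.7063e+01,2.7059e+01,1.5626e-01,5.6866e-01
1.2901e+01,2.3630e+01,2.2947e+01,2.2943e+01,1.5822e-01,5.2880e-01
1.3641e+01,2.0095e+01,1.9449e+01,1.9445e+01,1.6004e-01,4.9068e-01
1.4423e+01,1.7088e+01,1.6477e+01,1.6472e+01,1.6172e-01,4.5444e-01
1.5250e+01,1.4531e+01,1.3953e+01,1.3948e+01,1.6325e-01,4.2016e-01
1.6125e+01,1.2358e+01,1.1810e+01,1.1805e+01,1.6463e-01,3.8790e-01
1.7049e+01,1.0511e+01,9.9925e+00,9.9874e+00,1.6586e-01,3.5767e-01
1.8027e+01,8.9420e+00,8.4511e+00,8.4456e+00,1.6693e-01,3.2947e-01
1.9060e+01,7.6097e+00,7.1444e+00,7.1386e+00,1.6786e-01,3.0323e-01
2.0153e+01,6.4787e+00,6.0373e+00,6.0312e+00,1.6863e-01,2.7889e-01
2.1309e+01,5.5189e+00,5.0998e+00,5.0933e+00,1.6927e-01,2.5635e-01
2.2531e+01,4.7045e+00,4.3061e+00,4.2993e+00,1.6976e-01,2.3549e-01
2.3823e+01,4.0138e+00,3.6346e+00,3.6274e+00,1.7013e-01,2.1622e-01
2.5189e+01,3.4280e+00,3.0668e+00,3.0592e+00,1.7037e-01,1.9843e-01
2.6633e+01,2.9313e+00,2.5868e+00,2.5788e+00,1.7049e-01,1.8208e-01
2.8160e+01,2.5086e+00,2.1794e+00,2.1711e+00,1.7049e-01,1.6702e-01
2.9775e+01,2.1507e+00,1.8360e+00,1.8272e+00,1.7038e-01,1.5314e-01
3.1482e+01,1.8478e+00,1.5465e+00,1.5373e+00,1.7017e-01,1.4031e-01
3.3288e+01,1.5913e+00,1.3027e+00,1.2930e+00,1.6985e-01,1.2846e-01
3.5196e+01,1.3742e+00,1.0974e+00,1.0872e+00,1.6944e-01,1.1750e-01
3.7215e+01,1.1902e+00,9.2453e-01,9.1391e-01,1.6893e-01,1.0738e-01
3.9349e+01,1.0344e+00,7.7909e-01,7.6799e-01,1.6833e-01,9.8031e-02
4.1605e+01,9.0222e-01,6.5676e-01,6.4516e-01,1.6764e-01,8.9407e-02
4.3991e+01,7.9015e-01,5.5392e-01,5.4182e-01,1.6687e-01,8.1458e-02
4.6513e+01,6.9504e-01,4.6750e-01,4.5488e-01,1.6601e-01,7.4140e-02
4.9180e+01,6.1426e-01,3.9492e-01,3.8178e-01,1.6507e-01,6.7411e-02
5.2000e+01,5.4561e-01,3.3400e-01,3.2033e-01,1.6405e-01,6.1233e-02
5.4982e+01,4.8720e-01,2.8290e-01,2.6868e-01,1.6295e-01,5.5569e-02
5.8135e+01,4.3746e-01,2.4006e-01,2.2529e-01,1.6178e-01,5.0384e-02
6.1468e+01,3.9503e-01,2.0417e-01,1.8885e-01,1.6053e-01,4.5644e-02
6.4993e+01,3.5879e-01,1.7414e-01,1.5825e-01,1.5922e-01,4.1317e-02
6.8719e+01,3.2778e-01,1.4902e-01,1.3257e-01,1.5783e-01,3.7373e-02
7.2660e+01,3.0119e-01,1.2805e-01,1.1103e-01,1.5638e-01,3.3783e-02
7.6826e+01,2.7834e-01,1.1054e-01,9.2950e-02,1.5487e-01,3.0519e-02
8.1232e+01,2.5864e-01,9.5956e-02,7.7793e-02,1.5329e-01,2.7554e-02
8.5890e+01,2.4161e-01,8.3821e-02,6.5087e-02,1.5166e-01,2.4865e-02
9.0815e+01,2.2684e-01,7.3742e-02,5.4440e-02,1.4997e-01,2.2427e-02
9.6022e+01,2.1397e-01,6.5388e-02,4.5519e-02,1.4823e-01,2.0219e-02
1.0153e+02,2.0271e-01,5.8478e-02,3.8049e-02,1.4644e-01,1.8220e-02
1.0735e+02,1.9281e-01,5.2778e-02,3.1794e-02,1.4461e-01,1.6413e-02
1.1351e+02,1.8406e-01,4.8091e-02,2.6559e-02,1.4272e-01,1.4778e-02
1.2001e+02,1.7628e-01,4.4249e-02,2.2179e-02,1.4080e-01,1.3302e-02
1.2690e+02,1.6933e-01,4.1114e-02,1.8516e-02,1.3884e-01,1.1968e-02
1.3417e+02,1.6307e-01,3.8567e-02,1.5453e-02,1.3685e-01,1.0765e-02
1.4187e+02,1.5740e-01,3.6509e-02,1.2892e-02,1.3483e-01,9.6785e-03
1.5000e+02,1.5222e-01,3.4859e-02,1.0752e-02,1.3277e-01,8.6990e-03
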