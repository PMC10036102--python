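energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,7.1985e+02,7.1159e+02,7.1159e+02,5.7016e-02,8.2103e+00
5.2867e+00,6.2775e+02,6.1974e+02,6.1973e+02,5.9982e-02,7.9547e+00
5.5899e+00,5.4711e+02,5.3935e+02,5.3935e+02,6.2982e-02,7.6954e+00
5.9104e+00,4.7665e+02,4.6915e+02,4.6915e+02,6.6003e-02,7.4333e+00
6.2493e+00,4.1508e+02,4.0784e+02,4.0784e+02,6.9034e-02,7.1693e+00
6.6076e+00,3.6129e+02,3.5432e+02,3.5432e+02,7.2060e-02,6.9044e+00
6.9865e+00,3.1438e+02,3.0767e+02,3.0766e+02,7.5072e-02,6.6396e+00
7.3871e+00,2.7345e+02,2.6700e+02,2.6700e+02,7.8058e-02,6.3757e+00
7.8107e+00,2.3779e+02,2.3159e+02,2.3159e+02,8.1009e-02,6.1133e+00
8.2586e+00,2.0672e+02,2.0079e+02,2.0079e+02,8.3917e-02,5.8532e+00
8.7321e+00,1.7969e+02,1.7401e+02,1.7401e+02,8.6776e-02,5.5956e+00
9.2329e+00,1.5610e+02,1.5067e+02,1.5067e+02,8.9581e-02,5.3410e+00
9.7623e+00,1.3558e+02,1.3040e+02,1.3039e+02,9.2326e-02,5.0898e+00
1.0322e+01,1.1776e+02,1.1282e+02,1.1282e+02,9.5009e-02,4.8422e+00
1.0914e+01,1.0229e+02,9.7592e+01,9.7590e+01,9.7622e-02,4.5985e+00
1.1540e+01,8.8845e+01,8.4388e+01,8.4386e+01,1.0016e-01,4.3591e+00
1.2201e+01,7.7175e+01,7.2951e+01,7.2948e+01,1.0262e-01,4.1245e+00
1.2901e+01,6.7047e+01,6.3049e+01,6.3047e+01,1.0499e-01,3.8952e+00
1.3033e+01,6.5354e+01,6.1397e+01,6.1395e+01,1.0542e-01,3.8541e+00
1.3038e+01,1.6169e+02,1.5774e+02,1.5773e+02,1.0543e-01,3.8525e+00
1.3641e+01,1.4349e+02,1.3971e+02,1.3971e+02,1.0727e-01,3.6718e+00
1.4423e+01,1.2360e+02,1.2004e+02,1.2004e+02,1.0945e-01,3.4547e+00
1.5197e+01,1.0742e+02,1.0405e+02,1.0405e+02,1.1139e-01,3.2576e+00
1.5203e+01,1.4919e+02,1.4582e+02,1.4582e+02,1.1141e-01,3.2561e+00
1.5250e+01,1.4797e+02,1.4461e+02,1.4461e+02,1.1152e-01,3.2446e+00
1.5858e+01,1.3335e+02,1.3014e+02,1.3014e+02,1.1290e-01,3.1019e+00
1.5864e+01,1.5357e+02,1.5036e+02,1.5036e+02,1.1291e-01,3.1005e+00
1.6125e+01,1.4744e+02,1.4428e+02,1.4428e+02,1.1347e-01,3.0421e+00
1.7049e+01,1.2812e+02,1.2517e+02,1.2516e+02,1.1530e-01,2.8475e+00
1.8027e+01,1.1123e+02,1.0846e+02,1.0845e+02,1.1701e-01,2.6614e+00
1.9060e+01,9.6527e+01,9.3929e+01,9.3925e+01,1.1858e-01,2.4841e+00
2.0153e+01,8.3732e+01,8.1300e+01,8.1296e+01,1.2002e-01,2.3158e+00
2.1309e+01,7.2604e+01,7.0330e+01,7.0326e+01,1.2132e-01,2.1569e+00
2.2531e+01,6.2934e+01,6.0809e+01,6.0804e+01,1.2248e-01,2.0073e+00
2.3823e+01,5.4534e+01,5.2549e+01,5.2544e+01,1.2351e-01,1.8672e+00
2.5189e+01,4.7242e+01,4.5386e+01,4.5380e+01,1.2439e-01,1.7367e+00
2.6633e+01,4.0916e+01,3.9178e+01,3.9172e+01,1.2509e-01,1.6188e+00
2.8160e+01,3.5412e+01,3.3780e+01,3.3774e+01,1.2564e-01,1.5124e+00
2.9775e+01,3.0651e+01,2.9116e+01,2.9109e+01,1.2605e-01,1.4158e+00
3.1482e+01,2.6528e+01,2.5081e+01,2.5074e+01,1.2633e-01,1.3275e+00
3.3288e+01,2.2956e+01,2.1590e+01,2.1583e+01,1.2649e-01,1.2466e+00
3.5196e+01,1.9871e+01,1.8580e+01,1.8572e+01,1.2654e-01,1.1723e+00
3.7215e+01,1.7208e+01,1.5985e+01,1.5978e+01,1.2649e-01,1.1041e+00
3.9349e+01,1.4910e+01,1.3750e+01,1.3742e+01,1.2633e-01,1.0414e+00
4.1605e+01,1.2926e+01,1.1825e+01,1.1816e+01,1.2609e-01,9.8378e-01
4.3991e+01,1.1214e+01,1.0167e+01,1.0157e+01,1.2575e-01,9.3084e-01
4.6513e+01,9.7369e+00,8.7389e+00,8.7293e+00,1.2533e-01,8.8220e-01
4.9180e+01,8.4623e+00,7.5100e+00,7.5000e+00,1.2482e-01,8.3750e-01
5.2000e+01,7.3627e+00,6.4524e+00,6.4421e+00,1.2424e-01,7.9639e-01
5.4982e+01,6.4139e+00,5.5426e+00,5.5318e+00,1.2358e-01,7.5855e-01
5.8135e+01,5.5949e+00,4.7596e+00,4.7484e+00,1.2285e-01,7.2366e-01
6.1468e+01,4.8881e+00,4.0862e+00,4.0746e+00,1.2205e-01,6.9144e-01
6.4993e+01,4.2784e+00,3.5077e+00,3.4956e+00,1.2119e-01,6.6160e-01
6.8719e+01,3.7521e+00,3.0105e+00,2.9980e+00,1.2026e-01,6.3388e-01
7.2660e+01,3.2976e+00,2.5833e+00,2.5703e+00,1.1928e-01,6.0802e-01
7.6826e+01,2.9055e+00,2.2169e+00,2.2035e+00,1.1824e-01,5.8379e-01
8.1232e+01,2.5670e+00,1.9028e+00,1.8889e+00,1.1715e-01,5.6098e-01
8.5890e+01,2.2744e+00,1.6334e+00,1.6190e+00,1.1600e-01,5.3937e-01
8.7987e+01,2.1604e+00,1.5291e+00,1.5145e+00,1.1550e-01,5.3035e-01
8.8022e+01,7.8706e+00,7.2395e+00,7.2250e+00,1.1549e-01,5.3020e-01
9.0815e+01,7.3056e+00,6.6868e+00,6.6720e+00,1.1482e-01,5.1878e-01
9.6022e+01,6.3967e+00,5.7993e+00,5.7841e+00,1.1358e-01,4.9904e-01
1.0153e+02,5.6016e+00,5.0250e+00,5.0093e+00,1.1231e-01,4.7999e-01
1.0735e+02,4.9057e+00,4.3493e+00,4.3332e+00,1.1100e-01,4.6150e-01
1.1351e+02,4.2996e+00,3.7630e+00,3.7465e+00,1.0965e-01,4.4343e-01
1.2001e+02,3.7717e+00,3.2547e+00,3.2377e+00,1.0827e-01,4.2569e-01
1.2690e+02,3.3105e+00,2.8128e+00,2.7954e+00,1.0686e-01,4.0818e-01
1.3417e+02,2.9072e+00,2.4288e+00,2.4110e+00,1.0542e-01,3.9085e-01
1.4187e+02,2.5568e+00,2.0974e+00,2.0792e+00,1.0396e-01,3.7363e-01
1.5000e+02,2.2519e+00,1.8116e+00,1.7930e+00,1.0247e-01,3.5650e-01
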