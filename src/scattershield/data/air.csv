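energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,3.8759e+01,3.8111e+01,3.8110e+01,1.2654e-01,5.2201e-01
5.2867e+00,3.2860e+01,3.2241e+01,3.2240e+01,1.3072e-01,4.8941e-01
5.5899e+00,2.7853e+01,2.7261e+01,2.7260e+01,1.3468e-01,4.5826e-01
5.9104e+00,2.3605e+01,2.3039e+01,2.3038e+01,1.3844e-01,4.2861e-01
6.2493e+00,2.0002e+01,1.9461e+01,1.9459e+01,1.4196e-01,4.0050e-01
6.6076e+00,1.6947e+01,1.6429e+01,1.6427e+01,1.4527e-01,3.7396e-01
6.9865e+00,1.4358e+01,1.3863e+01,1.3861e+01,1.4835e-01,3.4897e-01
7.1106e+00,1.3626e+01,1.3137e+01,1.3135e+01,1.4924e-01,3.4139e-01
7.1134e+00,1.3609e+01,1.3121e+01,1.3119e+01,1.4926e-01,3.4122e-01
7.3871e+00,1.2166e+01,1.1691e+01,1.1689e+01,1.5120e-01,3.2551e-01
7.8107e+00,1.0310e+01,9.8551e+00,9.8528e+00,1.5384e-01,3.0355e-01
8.2586e+00,8.7402e+00,8.3033e+00,8.3009e+00,1.5628e-01,2.8301e-01
8.7321e+00,7.4127e+00,6.9930e+00,6.9904e+00,1.5851e-01,2.6383e-01
8.9772e+00,6.8297e+00,6.4182e+00,6.4154e+00,1.5952e-01,2.5478e-01
8.9808e+00,6.8217e+00,6.4102e+00,6.4075e+00,1.5953e-01,2.5465e-01
9.2329e+00,6.2870e+00,5.8833e+00,5.8805e+00,1.6055e-01,2.4592e-01
9.7623e+00,5.3353e+00,4.9467e+00,4.9437e+00,1.6241e-01,2.2921e-01
1.0322e+01,4.5320e+00,4.1575e+00,4.1543e+00,1.6411e-01,2.1359e-01
1.0914e+01,3.8543e+00,3.4930e+00,3.4896e+00,1.6564e-01,1.9898e-01
1.1540e+01,3.2829e+00,2.9342e+00,2.9306e+00,1.6703e-01,1.8531e-01
1.2201e+01,2.8012e+00,2.4643e+00,2.4605e+00,1.6828e-01,1.7249e-01
1.2901e+01,2.3951e+00,2.0693e+00,2.0652e+00,1.6941e-01,1.6046e-01
1.3033e+01,2.3283e+00,2.0045e+00,2.0004e+00,1.6959e-01,1.5834e-01
1.3038e+01,2.3258e+00,2.0020e+00,1.9979e+00,1.6959e-01,1.5825e-01
1.3641e+01,2.0526e+00,1.7374e+00,1.7331e+00,1.7041e-01,1.4914e-01
1.4423e+01,1.7636e+00,1.4584e+00,1.4538e+00,1.7129e-01,1.3850e-01
1.5197e+01,1.5338e+00,1.2375e+00,1.2327e+00,1.7201e-01,1.2909e-01
1.5203e+01,1.5322e+00,1.2360e+00,1.2312e+00,1.7202e-01,1.2902e-01
1.5250e+01,1.5198e+00,1.2240e+00,1.2192e+00,1.7206e-01,1.2848e-01
1.5858e+01,1.3719e+00,1.0826e+00,1.0776e+00,1.7253e-01,1.2180e-01
1.5864e+01,1.3705e+00,1.0813e+00,1.0762e+00,1.7253e-01,1.2173e-01
1.6125e+01,1.3140e+00,1.0273e+00,1.0222e+00,1.7273e-01,1.1905e-01
1.7049e+01,1.1403e+00,8.6225e-01,8.5686e-01,1.7329e-01,1.1016e-01
1.8027e+01,9.9363e-01,7.2377e-01,7.1808e-01,1.7375e-01,1.0180e-01
1.9060e+01,8.6968e-01,6.0764e-01,6.0164e-01,1.7411e-01,9.3931e-02
2.0153e+01,7.6488e-01,5.1029e-01,5.0396e-01,1.7438e-01,8.6539e-02
2.1309e+01,6.7619e-01,4.2871e-01,4.2204e-01,1.7455e-01,7.9606e-02
2.2531e+01,6.0109e-01,3.6037e-01,3.5335e-01,1.7463e-01,7.3113e-02
2.3823e+01,5.3743e-01,3.0315e-01,2.9576e-01,1.7462e-01,6.7045e-02
2.5189e+01,4.8341e-01,2.5527e-01,2.4751e-01,1.7451e-01,6.1387e-02
2.6633e+01,4.3752e-01,2.1523e-01,2.0707e-01,1.7432e-01,5.6127e-02
2.8160e+01,3.9826e-01,1.8153e-01,1.7297e-01,1.7404e-01,5.1251e-02
2.9775e+01,3.6487e-01,1.5344e-01,1.4446e-01,1.7366e-01,4.6744e-02
3.1482e+01,3.3643e-01,1.3005e-01,1.2064e-01,1.7321e-01,4.2586e-02
3.3288e+01,3.1216e-01,1.1059e-01,1.0074e-01,1.7266e-01,3.8760e-02
3.5196e+01,2.9139e-01,9.4414e-02,8.4111e-02,1.7204e-01,3.5245e-02
3.7215e+01,2.7357e-01,8.0990e-02,7.0221e-02,1.7133e-01,3.2021e-02
3.9349e+01,2.5823e-01,6.9865e-02,5.8619e-02,1.7054e-01,2.9070e-02
4.1605e+01,2.4498e-01,6.0664e-02,4.8928e-02,1.6968e-01,2.6370e-02
4.3991e+01,2.3348e-01,5.3071e-02,4.0835e-02,1.6874e-01,2.3905e-02
4.6513e+01,2.2346e-01,4.6824e-02,3.4077e-02,1.6773e-01,2.1655e-02
4.9180e+01,2.1469e-01,4.1701e-02,2.8434e-02,1.6665e-01,1.9604e-02
5.2000e+01,2.0695e-01,3.7519e-02,2.3723e-02,1.6550e-01,1.7735e-02
5.4982e+01,2.0010e-01,3.4123e-02,1.9790e-02,1.6428e-01,1.6035e-02
5.8135e+01,1.9399e-01,3.1385e-02,1.6507e-02,1.6299e-01,1.4488e-02
6.1468e+01,1.8849e-01,2.9197e-02,1.3767e-02,1.6164e-01,1.3083e-02
6.4993e+01,1.8352e-01,2.7467e-02,1.1480e-02,1.6023e-01,1.1806e-02
6.8719e+01,1.7898e-01,2.6120e-02,9.5724e-03,1.5876e-01,1.0648e-02
7.2660e+01,1.7481e-01,2.5093e-02,7.9805e-03,1.5723e-01,9.5986e-03
7.6826e+01,1.7094e-01,2.4331e-02,6.6525e-03,1.5564e-01,8.6475e-03
8.1232e+01,1.6733e-01,2.3791e-02,5.5447e-03,1.5400e-01,7.7866e-03
8.5890e+01,1.6393e-01,2.3434e-02,4.6208e-03,1.5231e-01,7.0079e-03
8.7987e+01,1.6251e-01,2.3342e-02,4.2701e-03,1.5155e-01,6.6942e-03
8.8022e+01,1.6249e-01,2.3341e-02,4.2645e-03,1.5154e-01,6.6891e-03
9.0815e+01,1.6072e-01,2.3229e-02,3.8503e-03,1.5056e-01,6.3040e-03
9.6022e+01,1.5765e-01,2.3149e-02,3.2079e-03,1.4877e-01,5.6683e-03
1.0153e+02,1.5470e-01,2.3171e-02,2.6723e-03,1.4694e-01,5.0945e-03
1.0735e+02,1.5186e-01,2.3276e-02,2.2258e-03,1.4506e-01,4.5770e-03
1.1351e+02,1.4910e-01,2.3447e-02,1.8537e-03,1.4314e-01,4.1105e-03
1.2001e+02,1.4642e-01,2.3673e-02,1.5435e-03,1.4118e-01,3.6903e-03
1.2690e+02,1.4379e-01,2.3939e-02,1.2851e-03,1.3919e-01,3.3120e-03
1.3417e+02,1.4121e-01,2.4237e-02,1.0698e-03,1.3717e-01,2.9716e-03
1.4187e+02,1.3867e-01,2.4559e-02,8.9042e-04,1.3512e-01,2.6654e-03
1.5000e+02,1.3617e-01,2.4896e-02,7.4103e-04,1.3304e-01,2.3902e-03
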