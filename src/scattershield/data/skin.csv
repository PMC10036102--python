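energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,3.7513e+01,3.6860e+01,3.6858e+01,1.4082e-01,5.1389e-01
5.2867e+00,3.1789e+01,3.1163e+01,3.1161e+01,1.4544e-01,4.8192e-01
5.5899e+00,2.6931e+01,2.6332e+01,2.6330e+01,1.4983e-01,4.5127e-01
5.9104e+00,2.2812e+01,2.2238e+01,2.2236e+01,1.5397e-01,4.2202e-01
6.2493e+00,1.9321e+01,1.8771e+01,1.8769e+01,1.5786e-01,3.9422e-01
6.6076e+00,1.6365e+01,1.5837e+01,1.5835e+01,1.6150e-01,3.6790e-01
6.9865e+00,1.3861e+01,1.3355e+01,1.3353e+01,1.6490e-01,3.4306e-01
7.1106e+00,1.3153e+01,1.2654e+01,1.2651e+01,1.6588e-01,3.3550e-01
7.1134e+00,1.3137e+01,1.2638e+01,1.2636e+01,1.6591e-01,3.3533e-01
7.3871e+00,1.1742e+01,1.1257e+01,1.1254e+01,1.6805e-01,3.1968e-01
7.8107e+00,9.9494e+00,9.4833e+00,9.4807e+00,1.7096e-01,2.9774e-01
8.2586e+00,8.4335e+00,7.9854e+00,7.9827e+00,1.7364e-01,2.7717e-01
8.7321e+00,7.1520e+00,6.7209e+00,6.7180e+00,1.7610e-01,2.5793e-01
8.9772e+00,6.5905e+00,6.1675e+00,6.1645e+00,1.7721e-01,2.4884e-01
8.9808e+00,6.5828e+00,6.1599e+00,6.1568e+00,1.7723e-01,2.4871e-01
9.2329e+00,6.0679e+00,5.6527e+00,5.6496e+00,1.7835e-01,2.3995e-01
9.7623e+00,5.1523e+00,4.7520e+00,4.7487e+00,1.8040e-01,2.2316e-01
1.0322e+01,4.3778e+00,3.9916e+00,3.9881e+00,1.8225e-01,2.0748e-01
1.0914e+01,3.7239e+00,3.3509e+00,3.3471e+00,1.8393e-01,1.9286e-01
1.1540e+01,3.1731e+00,2.8124e+00,2.8084e+00,1.8544e-01,1.7921e-01
1.2201e+01,2.7091e+00,2.3601e+00,2.3558e+00,1.8678e-01,1.6646e-01
1.2901e+01,2.3182e+00,1.9801e+00,1.9756e+00,1.8798e-01,1.5455e-01
1.3033e+01,2.2539e+00,1.9179e+00,1.9133e+00,1.8817e-01,1.5246e-01
1.3038e+01,2.2514e+00,1.9155e+00,1.9109e+00,1.8818e-01,1.5238e-01
1.3641e+01,1.9888e+00,1.6612e+00,1.6564e+00,1.8903e-01,1.4340e-01
1.4423e+01,1.7113e+00,1.3934e+00,1.3884e+00,1.8995e-01,1.3297e-01
1.5197e+01,1.4909e+00,1.1817e+00,1.1764e+00,1.9069e-01,1.2378e-01
1.5203e+01,1.4893e+00,1.1802e+00,1.1749e+00,1.9069e-01,1.2372e-01
1.5250e+01,1.4774e+00,1.1688e+00,1.1635e+00,1.9074e-01,1.2319e-01
1.5858e+01,1.3357e+00,1.0334e+00,1.0278e+00,1.9120e-01,1.1670e-01
1.5864e+01,1.3343e+00,1.0321e+00,1.0265e+00,1.9121e-01,1.1663e-01
1.6125e+01,1.2802e+00,9.8038e-01,9.7474e-01,1.9140e-01,1.1402e-01
1.7049e+01,1.1138e+00,8.2238e-01,8.1642e-01,1.9195e-01,1.0542e-01
1.8027e+01,9.7339e-01,6.8994e-01,6.8364e-01,1.9239e-01,9.7352e-02
1.9060e+01,8.5482e-01,5.7897e-01,5.7232e-01,1.9272e-01,8.9783e-02
2.0153e+01,7.5464e-01,4.8602e-01,4.7901e-01,1.9294e-01,8.2689e-02
2.1309e+01,6.6991e-01,4.0819e-01,4.0082e-01,1.9305e-01,7.6048e-02
2.2531e+01,5.9821e-01,3.4307e-01,3.3530e-01,1.9306e-01,6.9842e-02
2.3823e+01,5.3746e-01,2.8859e-01,2.8043e-01,1.9298e-01,6.4053e-02
2.5189e+01,4.8593e-01,2.4305e-01,2.3447e-01,1.9279e-01,5.8664e-02
2.6633e+01,4.4216e-01,2.0501e-01,1.9600e-01,1.9251e-01,5.3650e-02
2.8160e+01,4.0466e-01,1.7298e-01,1.6353e-01,1.9214e-01,4.8997e-02
2.9775e+01,3.7278e-01,1.4633e-01,1.3642e-01,1.9167e-01,4.4691e-02
3.1482e+01,3.4562e-01,1.2417e-01,1.1379e-01,1.9111e-01,4.0716e-02
3.3288e+01,3.2243e-01,1.0578e-01,9.4916e-02,1.9046e-01,3.7055e-02
3.5196e+01,3.0258e-01,9.0527e-02,7.9165e-02,1.8972e-01,3.3690e-02
3.7215e+01,2.8553e-01,7.7898e-02,6.6024e-02,1.8890e-01,3.0603e-02
3.9349e+01,2.7084e-01,6.7459e-02,5.5061e-02,1.8800e-01,2.7777e-02
4.1605e+01,2.5812e-01,5.8850e-02,4.5915e-02,1.8701e-01,2.5192e-02
4.3991e+01,2.4706e-01,5.1770e-02,3.8286e-02,1.8594e-01,2.2832e-02
4.6513e+01,2.3740e-01,4.5967e-02,3.1923e-02,1.8480e-01,2.0678e-02
4.9180e+01,2.2891e-01,4.1230e-02,2.6615e-02,1.8358e-01,1.8716e-02
5.2000e+01,2.2140e-01,3.7384e-02,2.2188e-02,1.8228e-01,1.6929e-02
5.4982e+01,2.1472e-01,3.4282e-02,1.8497e-02,1.8092e-01,1.5304e-02
5.8135e+01,2.0873e-01,3.1802e-02,1.5418e-02,1.7948e-01,1.3826e-02
6.1468e+01,2.0331e-01,2.9840e-02,1.2851e-02,1.7798e-01,1.2484e-02
6.4993e+01,1.9838e-01,2.8311e-02,1.0711e-02,1.7640e-01,1.1266e-02
6.8719e+01,1.9385e-01,2.7143e-02,8.9263e-03,1.7477e-01,1.0160e-02
7.2660e+01,1.8966e-01,2.6275e-02,7.4385e-03,1.7307e-01,9.1587e-03
7.6826e+01,1.8576e-01,2.5657e-02,6.1983e-03,1.7131e-01,8.2514e-03
8.1232e+01,1.8208e-01,2.5246e-02,5.1644e-03,1.6949e-01,7.4301e-03
8.5890e+01,1.7860e-01,2.5007e-02,4.3027e-03,1.6761e-01,6.6873e-03
8.7987e+01,1.7714e-01,2.4963e-02,3.9758e-03,1.6678e-01,6.3881e-03
8.8022e+01,1.7712e-01,2.4962e-02,3.9706e-03,1.6676e-01,6.3832e-03
9.0815e+01,1.7529e-01,2.4910e-02,3.5845e-03,1.6569e-01,6.0160e-03
9.6022e+01,1.7210e-01,2.4928e-02,2.9860e-03,1.6371e-01,5.4096e-03
1.0153e+02,1.6903e-01,2.5042e-02,2.4872e-03,1.6168e-01,4.8622e-03
1.0735e+02,1.6604e-01,2.5232e-02,2.0716e-03,1.5960e-01,4.3685e-03
1.1351e+02,1.6313e-01,2.5483e-02,1.7253e-03,1.5749e-01,3.9235e-03
1.2001e+02,1.6029e-01,2.5783e-02,1.4368e-03,1.5533e-01,3.5226e-03
1.2690e+02,1.5749e-01,2.6119e-02,1.1964e-03,1.5313e-01,3.1616e-03
1.3417e+02,1.5474e-01,2.6483e-02,9.9616e-04,1.5090e-01,2.8367e-03
1.4187e+02,1.5202e-01,2.6867e-02,8.2938e-04,1.4864e-01,2.5445e-03
1.5000e+02,1.4932e-01,2.7262e-02,6.9047e-04,1.4635e-01,2.2818e-03
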