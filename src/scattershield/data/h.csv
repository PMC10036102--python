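energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,3.9071e-01,2.7768e-03,1.0000e-12,2.8989e-01,1.0082e-01
5.2867e+00,3.9020e-01,3.0103e-03,1.0000e-12,2.9759e-01,9.2618e-02
5.5899e+00,3.8968e-01,3.2553e-03,1.0000e-12,3.0474e-01,8.4942e-02
5.9104e+00,3.8914e-01,3.5120e-03,1.0000e-12,3.1136e-01,7.7782e-02
6.2493e+00,3.8858e-01,3.7807e-03,1.0000e-12,3.1745e-01,7.1126e-02
6.6076e+00,3.8799e-01,4.0617e-03,1.0000e-12,3.2303e-01,6.4959e-02
6.9865e+00,3.8739e-01,4.3555e-03,1.0000e-12,3.2813e-01,5.9258e-02
7.3871e+00,3.8676e-01,4.6624e-03,1.0000e-12,3.3276e-01,5.3999e-02
7.8107e+00,3.8610e-01,4.9830e-03,1.0000e-12,3.3694e-01,4.9156e-02
8.2586e+00,3.8542e-01,5.3178e-03,1.0000e-12,3.4071e-01,4.4704e-02
8.7321e+00,3.8470e-01,5.6673e-03,1.0000e-12,3.4409e-01,4.0616e-02
9.2329e+00,3.8396e-01,6.0321e-03,1.0000e-12,3.4709e-01,3.6867e-02
9.7623e+00,3.8318e-01,6.4129e-03,1.0000e-12,3.4975e-01,3.3433e-02
1.0322e+01,3.8237e-01,6.8101e-03,1.0000e-12,3.5208e-01,3.0290e-02
1.0914e+01,3.8152e-01,7.2244e-03,1.0000e-12,3.5410e-01,2.7419e-02
1.1540e+01,3.8063e-01,7.6564e-03,1.0000e-12,3.5583e-01,2.4799e-02
1.2201e+01,3.7970e-01,8.1066e-03,1.0000e-12,3.5729e-01,2.2411e-02
1.2901e+01,3.7872e-01,8.5758e-03,1.0000e-12,3.5849e-01,2.0236e-02
1.3641e+01,3.7770e-01,9.0646e-03,1.0000e-12,3.5944e-01,1.8260e-02
1.4423e+01,3.7663e-01,9.5734e-03,1.0000e-12,3.6017e-01,1.6464e-02
1.5250e+01,3.7551e-01,1.0103e-02,1.0000e-12,3.6067e-01,1.4835e-02
1.6125e+01,3.7434e-01,1.0654e-02,1.0000e-12,3.6098e-01,1.3360e-02
1.7049e+01,3.7311e-01,1.1227e-02,1.0000e-12,3.6108e-01,1.2023e-02
1.8027e+01,3.7182e-01,1.1822e-02,1.0000e-12,3.6100e-01,1.0815e-02
1.9060e+01,3.7047e-01,1.2440e-02,1.0000e-12,3.6075e-01,9.7231e-03
2.0153e+01,3.6906e-01,1.3081e-02,1.0000e-12,3.6032e-01,8.7374e-03
2.1309e+01,3.6759e-01,1.3747e-02,1.0000e-12,3.5974e-01,7.8483e-03
2.2531e+01,3.6604e-01,1.4436e-02,1.0000e-12,3.5900e-01,7.0469e-03
2.3823e+01,3.6443e-01,1.5150e-02,1.0000e-12,3.5811e-01,6.3251e-03
2.5189e+01,3.6275e-01,1.5889e-02,1.0000e-12,3.5708e-01,5.6753e-03
2.6633e+01,3.6100e-01,1.6653e-02,1.0000e-12,3.5591e-01,5.0907e-03
2.8160e+01,3.5917e-01,1.7442e-02,1.0000e-12,3.5460e-01,4.5649e-03
2.9775e+01,3.5726e-01,1.8256e-02,1.0000e-12,3.5317e-01,4.0924e-03
3.1482e+01,3.5527e-01,1.9095e-02,1.0000e-12,3.5160e-01,3.6680e-03
3.3288e+01,3.5320e-01,1.9958e-02,1.0000e-12,3.4991e-01,3.2869e-03
3.5196e+01,3.5105e-01,2.0846e-02,1.0000e-12,3.4810e-01,2.9448e-03
3.7215e+01,3.4881e-01,2.1758e-02,1.0000e-12,3.4617e-01,2.6380e-03
3.9349e+01,3.4648e-01,2.2694e-02,1.0000e-12,3.4412e-01,2.3627e-03
4.1605e+01,3.4407e-01,2.3652e-02,1.0000e-12,3.4196e-01,2.1159e-03
4.3991e+01,3.4157e-01,2.4631e-02,1.0000e-12,3.3968e-01,1.8946e-03
4.6513e+01,3.3898e-01,2.5632e-02,1.0000e-12,3.3728e-01,1.6963e-03
4.9180e+01,3.3630e-01,2.6652e-02,1.0000e-12,3.3478e-01,1.5187e-03
5.2000e+01,3.3353e-01,2.7690e-02,1.0000e-12,3.3217e-01,1.3595e-03
5.4982e+01,3.3066e-01,2.8745e-02,1.0000e-12,3.2945e-01,1.2168e-03
5.8135e+01,3.2771e-01,2.9815e-02,1.0000e-12,3.2662e-01,1.0891e-03
6.1468e+01,3.2466e-01,3.0898e-02,1.0000e-12,3.2369e-01,9.7473e-04
6.4993e+01,3.2152e-01,3.1992e-02,1.0000e-12,3.2065e-01,8.7231e-04
6.8719e+01,3.1830e-01,3.3096e-02,1.0000e-12,3.1752e-01,7.8061e-04
7.2660e+01,3.1499e-01,3.4206e-02,1.0000e-12,3.1429e-01,6.9852e-04
7.6826e+01,3.1158e-01,3.5322e-02,1.0000e-12,3.1096e-01,6.2503e-04
8.1232e+01,3.0810e-01,3.6439e-02,1.0000e-12,3.0754e-01,5.5925e-04
8.5890e+01,3.0453e-01,3.7555e-02,1.0000e-12,3.0403e-01,5.0038e-04
9.0815e+01,3.0088e-01,3.8669e-02,1.0000e-12,3.0044e-01,4.4769e-04
9.6022e+01,2.9716e-01,3.9777e-02,1.0000e-12,2.9676e-01,4.0054e-04
1.0153e+02,2.9336e-01,4.0875e-02,1.0000e-12,2.9300e-01,3.5834e-04
1.0735e+02,2.8949e-01,4.1963e-02,1.0000e-12,2.8917e-01,3.2058e-04
1.1351e+02,2.8556e-01,4.3036e-02,1.0000e-12,2.8527e-01,2.8679e-04
1.2001e+02,2.8156e-01,4.4092e-02,1.0000e-12,2.8131e-01,2.5656e-04
1.2690e+02,2.7751e-01,4.5128e-02,1.0000e-12,2.7728e-01,2.2952e-04
1.3417e+02,2.7340e-01,4.6142e-02,1.0000e-12,2.7319e-01,2.0532e-04
1.4187e+02,2.6924e-01,4.7130e-02,1.0000e-12,2.6906e-01,1.8366e-04
1.5000e+02,2.6504e-01,4.8091e-02,1.0000e-12,2.6488e-01,1.6429e-04
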