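energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,4.2203e+02,4.2052e+02,4.2052e+02,9.9869e-02,1.4087e+00
5.2867e+00,3.6364e+02,3.6220e+02,3.6220e+02,1.0334e-01,1.3426e+00
5.5899e+00,3.1307e+02,3.1168e+02,3.1168e+02,1.0667e-01,1.2788e+00
5.9104e+00,2.6929e+02,2.6797e+02,2.6797e+02,1.0986e-01,1.2175e+00
6.2493e+00,2.3144e+02,2.3017e+02,2.3017e+02,1.1289e-01,1.1587e+00
6.6076e+00,1.9869e+02,1.9747e+02,1.9747e+02,1.1578e-01,1.1022e+00
6.9865e+00,1.7041e+02,1.6925e+02,1.6925e+02,1.1854e-01,1.0480e+00
7.3871e+00,1.4607e+02,1.4496e+02,1.4496e+02,1.2117e-01,9.9587e-01
7.8107e+00,1.2513e+02,1.2406e+02,1.2406e+02,1.2367e-01,9.4561e-01
8.2586e+00,1.0713e+02,1.0610e+02,1.0610e+02,1.2607e-01,8.9705e-01
8.7321e+00,9.1655e+01,9.0679e+01,9.0677e+01,1.2837e-01,8.4998e-01
9.2329e+00,7.8336e+01,7.7404e+01,7.7401e+01,1.3057e-01,8.0425e-01
9.7623e+00,6.6907e+01,6.6017e+01,6.6015e+01,1.3269e-01,7.5973e-01
1.0322e+01,5.7122e+01,5.6274e+01,5.6271e+01,1.3472e-01,7.1635e-01
1.0914e+01,4.8749e+01,4.7941e+01,4.7938e+01,1.3667e-01,6.7406e-01
1.1540e+01,4.1588e+01,4.0819e+01,4.0816e+01,1.3854e-01,6.3286e-01
1.2201e+01,3.5466e+01,3.4736e+01,3.4732e+01,1.4032e-01,5.9280e-01
1.2901e+01,3.0234e+01,2.9542e+01,2.9538e+01,1.4200e-01,5.5395e-01
1.3641e+01,2.5767e+01,2.5110e+01,2.5107e+01,1.4359e-01,5.1639e-01
1.4423e+01,2.1940e+01,2.1319e+01,2.1315e+01,1.4508e-01,4.8024e-01
1.5250e+01,1.8675e+01,1.8087e+01,1.8083e+01,1.4646e-01,4.4560e-01
1.6125e+01,1.5895e+01,1.5339e+01,1.5335e+01,1.4772e-01,4.1258e-01
1.7049e+01,1.3529e+01,1.3003e+01,1.2998e+01,1.4886e-01,3.8127e-01
1.8027e+01,1.1515e+01,1.1018e+01,1.1013e+01,1.4987e-01,3.5173e-01
1.9060e+01,9.8023e+00,9.3327e+00,9.3275e+00,1.5076e-01,3.2402e-01
2.0153e+01,8.3459e+00,7.9017e+00,7.8962e+00,1.5152e-01,2.9814e-01
2.1309e+01,7.1079e+00,6.6875e+00,6.6817e+00,1.5215e-01,2.7408e-01
2.2531e+01,6.0560e+00,5.6577e+00,5.6515e+00,1.5265e-01,2.5181e-01
2.3823e+01,5.1624e+00,4.7846e+00,4.7781e+00,1.5303e-01,2.3124e-01
2.5189e+01,4.4035e+00,4.0447e+00,4.0379e+00,1.5329e-01,2.1232e-01
2.6633e+01,3.7593e+00,3.4181e+00,3.4109e+00,1.5343e-01,1.9503e-01
2.8160e+01,3.2126e+00,2.8875e+00,2.8799e+00,1.5346e-01,1.7917e-01
2.9775e+01,2.7485e+00,2.4385e+00,2.4305e+00,1.5339e-01,1.6458e-01
3.1482e+01,2.3547e+00,2.0587e+00,2.0504e+00,1.5322e-01,1.5111e-01
3.3288e+01,2.0205e+00,1.7376e+00,1.7289e+00,1.5295e-01,1.3865e-01
3.5196e+01,1.7370e+00,1.4664e+00,1.4572e+00,1.5260e-01,1.2713e-01
3.7215e+01,1.4963e+00,1.2372e+00,1.2277e+00,1.5216e-01,1.1647e-01
3.9349e+01,1.2921e+00,1.0438e+00,1.0338e+00,1.5164e-01,1.0661e-01
4.1605e+01,1.1187e+00,8.8066e-01,8.7021e-01,1.5104e-01,9.7484e-02
4.3991e+01,9.7158e-01,7.4307e-01,7.3216e-01,1.5036e-01,8.9054e-02
4.6513e+01,8.4661e-01,6.2711e-01,6.1574e-01,1.4961e-01,8.1271e-02
4.9180e+01,7.4046e-01,5.2944e-01,5.1760e-01,1.4877e-01,7.4091e-02
5.2000e+01,6.5025e-01,4.4723e-01,4.3491e-01,1.4787e-01,6.7476e-02
5.4982e+01,5.7355e-01,3.7808e-01,3.6526e-01,1.4690e-01,6.1388e-02
5.8135e+01,5.0829e-01,3.1995e-01,3.0664e-01,1.4586e-01,5.5795e-02
6.1468e+01,4.5271e-01,2.7112e-01,2.5730e-01,1.4475e-01,5.0662e-02
6.4993e+01,4.0534e-01,2.3014e-01,2.1581e-01,1.4357e-01,4.5960e-02
6.8719e+01,3.6492e-01,1.9576e-01,1.8093e-01,1.4234e-01,4.1657e-02
7.2660e+01,3.3039e-01,1.6697e-01,1.5162e-01,1.4104e-01,3.7727e-02
7.6826e+01,3.0083e-01,1.4286e-01,1.2700e-01,1.3969e-01,3.4143e-02
8.1232e+01,2.7548e-01,1.2271e-01,1.0633e-01,1.3828e-01,3.0877e-02
8.5890e+01,2.5370e-01,1.0588e-01,8.8981e-02,1.3682e-01,2.7906e-02
9.0815e+01,2.3494e-01,9.1847e-02,7.4432e-02,1.3530e-01,2.5206e-02
9.6022e+01,2.1873e-01,8.0160e-02,6.2234e-02,1.3374e-01,2.2755e-02
1.0153e+02,2.0468e-01,7.0445e-02,5.2011e-02,1.3214e-01,2.0532e-02
1.0735e+02,1.9245e-01,6.2383e-02,4.3448e-02,1.3049e-01,1.8518e-02
1.1351e+02,1.8177e-01,5.5709e-02,3.6279e-02,1.2880e-01,1.6693e-02
1.2001e+02,1.7239e-01,5.0195e-02,3.0279e-02,1.2707e-01,1.5042e-02
1.2690e+02,1.6412e-01,4.5654e-02,2.5259e-02,1.2531e-01,1.3549e-02
1.3417e+02,1.5677e-01,4.1924e-02,2.1063e-02,1.2351e-01,1.2200e-02
1.4187e+02,1.5022e-01,3.8872e-02,1.7556e-02,1.2169e-01,1.0980e-02
1.5000e+02,1.4434e-01,3.6384e-02,1.4626e-02,1.1984e-01,9.8787e-03
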