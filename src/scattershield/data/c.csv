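energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,1.8137e+01,1.7641e+01,1.7640e+01,1.3706e-01,3.5947e-01
5.2867e+00,1.5307e+01,1.4830e+01,1.4829e+01,1.4051e-01,3.3735e-01
5.5899e+00,1.2913e+01,1.2455e+01,1.2453e+01,1.4374e-01,3.1647e-01
5.9104e+00,1.0897e+01,1.0455e+01,1.0454e+01,1.4676e-01,2.9684e-01
6.2493e+00,9.1999e+00,8.7737e+00,8.7719e+00,1.4957e-01,2.7839e-01
6.6076e+00,7.7714e+00,7.3601e+00,7.3581e+00,1.5218e-01,2.6110e-01
6.9865e+00,6.5695e+00,6.1721e+00,6.1700e+00,1.5459e-01,2.4489e-01
7.3871e+00,5.5585e+00,5.1741e+00,5.1719e+00,1.5682e-01,2.2971e-01
7.8107e+00,4.7081e+00,4.3361e+00,4.3337e+00,1.5887e-01,2.1547e-01
8.2586e+00,3.9930e+00,3.6326e+00,3.6301e+00,1.6077e-01,2.0212e-01
8.7321e+00,3.3917e+00,3.0423e+00,3.0396e+00,1.6251e-01,1.8957e-01
9.2329e+00,2.8835e+00,2.5445e+00,2.5416e+00,1.6411e-01,1.7776e-01
9.7623e+00,2.4558e+00,2.1266e+00,2.1236e+00,1.6559e-01,1.6663e-01
1.0322e+01,2.0971e+00,1.7773e+00,1.7740e+00,1.6694e-01,1.5611e-01
1.0914e+01,1.7961e+00,1.4852e+00,1.4818e+00,1.6817e-01,1.4614e-01
1.1540e+01,1.5434e+00,1.2411e+00,1.2374e+00,1.6930e-01,1.3667e-01
1.2201e+01,1.3312e+00,1.0371e+00,1.0332e+00,1.7033e-01,1.2768e-01
1.2901e+01,1.1529e+00,8.6662e-01,8.6252e-01,1.7126e-01,1.1911e-01
1.3641e+01,1.0030e+00,7.2426e-01,7.1992e-01,1.7210e-01,1.1094e-01
1.4423e+01,8.7680e-01,6.0538e-01,6.0079e-01,1.7285e-01,1.0316e-01
1.5250e+01,7.7054e-01,5.0615e-01,5.0129e-01,1.7351e-01,9.5744e-02
1.6125e+01,6.8095e-01,4.2333e-01,4.1819e-01,1.7408e-01,8.8688e-02
1.7049e+01,6.0535e-01,3.5424e-01,3.4881e-01,1.7455e-01,8.1989e-02
1.8027e+01,5.4148e-01,2.9662e-01,2.9089e-01,1.7494e-01,7.5644e-02
1.9060e+01,4.8744e-01,2.4859e-01,2.4254e-01,1.7524e-01,6.9654e-02
2.0153e+01,4.4167e-01,2.0857e-01,2.0220e-01,1.7545e-01,6.4020e-02
2.1309e+01,4.0284e-01,1.7524e-01,1.6853e-01,1.7557e-01,5.8743e-02
2.2531e+01,3.6986e-01,1.4751e-01,1.4045e-01,1.7559e-01,5.3820e-02
2.3823e+01,3.4179e-01,1.2445e-01,1.1703e-01,1.7552e-01,4.9246e-02
2.5189e+01,3.1786e-01,1.0530e-01,9.7493e-02,1.7536e-01,4.5012e-02
2.6633e+01,2.9740e-01,8.9399e-02,8.1206e-02,1.7511e-01,4.1087e-02
2.8160e+01,2.7972e-01,7.6090e-02,6.7494e-02,1.7477e-01,3.7455e-02
2.9775e+01,2.6455e-01,6.5107e-02,5.6094e-02,1.7435e-01,3.4106e-02
3.1482e+01,2.5150e-01,5.6064e-02,4.6623e-02,1.7385e-01,3.1024e-02
3.3288e+01,2.4021e-01,4.8635e-02,3.8752e-02,1.7326e-01,2.8195e-02
3.5196e+01,2.3041e-01,4.2548e-02,3.2212e-02,1.7260e-01,2.5602e-02
3.7215e+01,2.2186e-01,3.7579e-02,2.6777e-02,1.7185e-01,2.3229e-02
3.9349e+01,2.1435e-01,3.3539e-02,2.2260e-02,1.7103e-01,2.1061e-02
4.1605e+01,2.0773e-01,3.0273e-02,1.8506e-02,1.7014e-01,1.9081e-02
4.3991e+01,2.0183e-01,2.7653e-02,1.5385e-02,1.6917e-01,1.7275e-02
4.6513e+01,1.9655e-01,2.5569e-02,1.2792e-02,1.6813e-01,1.5629e-02
4.9180e+01,1.9179e-01,2.3933e-02,1.0636e-02,1.6703e-01,1.4130e-02
5.2000e+01,1.8746e-01,2.2670e-02,8.8440e-03,1.6585e-01,1.2766e-02
5.4982e+01,1.8349e-01,2.1717e-02,7.3542e-03,1.6461e-01,1.1527e-02
5.8135e+01,1.7982e-01,2.1023e-02,6.1157e-03,1.6331e-01,1.0401e-02
6.1468e+01,1.7640e-01,2.0544e-02,5.0860e-03,1.6194e-01,9.3795e-03
6.4993e+01,1.7319e-01,2.0244e-02,4.2298e-03,1.6051e-01,8.4531e-03
6.8719e+01,1.7015e-01,2.0093e-02,3.5180e-03,1.5902e-01,7.6139e-03
7.2660e+01,1.6726e-01,2.0066e-02,2.9261e-03,1.5748e-01,6.8542e-03
7.6826e+01,1.6448e-01,2.0140e-02,2.4339e-03,1.5588e-01,6.1672e-03
8.1232e+01,1.6179e-01,2.0298e-02,2.0245e-03,1.5422e-01,5.5462e-03
8.5890e+01,1.5919e-01,2.0524e-02,1.6842e-03,1.5252e-01,4.9855e-03
9.0815e+01,1.5665e-01,2.0806e-02,1.4011e-03,1.5077e-01,4.4796e-03
9.6022e+01,1.5415e-01,2.1132e-02,1.1656e-03,1.4896e-01,4.0233e-03
1.0153e+02,1.5170e-01,2.1494e-02,9.6976e-04,1.4712e-01,3.6122e-03
1.0735e+02,1.4928e-01,2.1882e-02,8.0686e-04,1.4523e-01,3.2420e-03
1.1351e+02,1.4689e-01,2.2290e-02,6.7136e-04,1.4331e-01,2.9088e-03
1.2001e+02,1.4451e-01,2.2713e-02,5.5864e-04,1.4134e-01,2.6091e-03
1.2690e+02,1.4215e-01,2.3144e-02,4.6486e-04,1.3935e-01,2.3396e-03
1.3417e+02,1.3980e-01,2.3579e-02,3.8685e-04,1.3732e-01,2.0975e-03
1.4187e+02,1.3746e-01,2.4015e-02,3.2194e-04,1.3526e-01,1.8800e-03
1.5000e+02,1.3513e-01,2.4447e-02,2.6794e-04,1.3318e-01,1.6847e-03
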