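energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,2.8280e+02,2.8145e+02,2.8145e+02,1.0904e-01,1.2368e+00
5.2867e+00,2.4230e+02,2.4101e+02,2.4100e+02,1.1217e-01,1.1867e+00
5.5899e+00,2.0748e+02,2.0623e+02,2.0623e+02,1.1524e-01,1.1375e+00
5.9104e+00,1.7755e+02,1.7634e+02,1.7634e+02,1.1825e-01,1.0889e+00
6.2493e+00,1.5184e+02,1.5068e+02,1.5068e+02,1.2121e-01,1.0409e+00
6.6076e+00,1.2978e+02,1.2867e+02,1.2867e+02,1.2412e-01,9.9328e-01
6.9865e+00,1.1086e+02,1.0979e+02,1.0979e+02,1.2699e-01,9.4607e-01
7.3871e+00,9.4642e+01,9.3614e+01,9.3613e+01,1.2982e-01,8.9921e-01
7.8107e+00,8.0750e+01,7.9766e+01,7.9764e+01,1.3260e-01,8.5272e-01
8.2586e+00,6.8859e+01,6.7919e+01,6.7917e+01,1.3533e-01,8.0666e-01
8.7321e+00,5.8686e+01,5.7790e+01,5.7787e+01,1.3800e-01,7.6115e-01
9.2329e+00,4.9984e+01,4.9130e+01,4.9127e+01,1.4061e-01,7.1634e-01
9.7623e+00,4.2516e+01,4.1703e+01,4.1700e+01,1.4313e-01,6.7239e-01
1.0322e+01,3.6151e+01,3.5379e+01,3.5376e+01,1.4556e-01,6.2951e-01
1.0914e+01,3.0735e+01,3.0002e+01,2.9999e+01,1.4789e-01,5.8788e-01
1.1540e+01,2.6126e+01,2.5431e+01,2.5428e+01,1.5009e-01,5.4770e-01
1.2201e+01,2.2206e+01,2.1548e+01,2.1544e+01,1.5216e-01,5.0913e-01
1.2901e+01,1.8873e+01,1.8250e+01,1.8246e+01,1.5409e-01,4.7234e-01
1.3641e+01,1.6040e+01,1.5450e+01,1.5446e+01,1.5588e-01,4.3742e-01
1.4423e+01,1.3632e+01,1.3075e+01,1.3070e+01,1.5751e-01,4.0446e-01
1.5250e+01,1.1588e+01,1.1060e+01,1.1055e+01,1.5898e-01,3.7348e-01
1.6125e+01,9.8516e+00,9.3515e+00,9.3468e+00,1.6030e-01,3.4449e-01
1.7049e+01,8.3779e+00,7.9040e+00,7.8990e+00,1.6146e-01,3.1745e-01
1.8027e+01,7.1273e+00,6.6779e+00,6.6725e+00,1.6247e-01,2.9230e-01
1.9060e+01,6.0664e+00,5.6397e+00,5.6341e+00,1.6334e-01,2.6896e-01
2.0153e+01,5.1666e+00,4.7611e+00,4.7552e+00,1.6406e-01,2.4733e-01
2.1309e+01,4.4036e+00,4.0179e+00,4.0117e+00,1.6465e-01,2.2732e-01
2.2531e+01,3.7568e+00,3.3896e+00,3.3829e+00,1.6510e-01,2.0882e-01
2.3823e+01,3.2087e+00,2.8585e+00,2.8515e+00,1.6543e-01,1.9174e-01
2.5189e+01,2.7441e+00,2.4099e+00,2.4025e+00,1.6564e-01,1.7599e-01
2.6633e+01,2.3505e+00,2.0311e+00,2.0233e+00,1.6573e-01,1.6148e-01
2.8160e+01,2.0156e+00,1.7100e+00,1.7018e+00,1.6571e-01,1.4809e-01
2.9775e+01,1.7323e+00,1.4395e+00,1.4310e+00,1.6559e-01,1.3571e-01
3.1482e+01,1.4925e+00,1.2118e+00,1.2028e+00,1.6537e-01,1.2426e-01
3.3288e+01,1.2895e+00,1.0202e+00,1.0108e+00,1.6505e-01,1.1368e-01
3.5196e+01,1.1177e+00,8.5899e-01,8.4913e-01,1.6464e-01,1.0390e-01
3.7215e+01,9.7212e-01,7.2343e-01,7.1312e-01,1.6413e-01,9.4869e-02
3.9349e+01,8.4878e-01,6.0949e-01,5.9871e-01,1.6354e-01,8.6534e-02
4.1605e+01,7.4422e-01,5.1377e-01,5.0250e-01,1.6286e-01,7.8849e-02
4.3991e+01,6.5550e-01,4.3339e-01,4.2163e-01,1.6210e-01,7.1773e-02
4.6513e+01,5.8019e-01,3.6592e-01,3.5367e-01,1.6126e-01,6.5266e-02
4.9180e+01,5.1619e-01,3.0933e-01,2.9657e-01,1.6033e-01,5.9290e-02
5.2000e+01,4.6176e-01,2.6190e-01,2.4861e-01,1.5933e-01,5.3810e-02
5.4982e+01,4.1540e-01,2.2216e-01,2.0835e-01,1.5826e-01,4.8793e-02
5.8135e+01,3.7587e-01,1.8890e-01,1.7455e-01,1.5711e-01,4.4206e-02
6.1468e+01,3.4211e-01,1.6108e-01,1.4620e-01,1.5590e-01,4.0019e-02
6.4993e+01,3.1322e-01,1.3783e-01,1.2241e-01,1.5461e-01,3.6202e-02
6.8719e+01,2.8845e-01,1.1844e-01,1.0246e-01,1.5326e-01,3.2727e-02
7.2660e+01,2.6715e-01,1.0226e-01,8.5738e-02,1.5184e-01,2.9567e-02
7.6826e+01,2.4879e-01,8.8803e-02,7.1723e-02,1.5037e-01,2.6697e-02
8.1232e+01,2.3291e-01,7.7616e-02,5.9981e-02,1.4884e-01,2.4093e-02
8.5890e+01,2.1912e-01,6.8335e-02,5.0147e-02,1.4725e-01,2.1733e-02
9.0815e+01,2.0711e-01,6.0653e-02,4.1912e-02,1.4560e-01,1.9595e-02
9.6022e+01,1.9659e-01,5.4309e-02,3.5020e-02,1.4391e-01,1.7659e-02
1.0153e+02,1.8733e-01,4.9085e-02,2.9252e-02,1.4217e-01,1.5908e-02
1.0735e+02,1.7913e-01,4.4798e-02,2.4427e-02,1.4038e-01,1.4325e-02
1.1351e+02,1.7184e-01,4.1294e-02,2.0392e-02,1.3855e-01,1.2895e-02
1.2001e+02,1.6531e-01,3.8443e-02,1.7019e-02,1.3668e-01,1.1603e-02
1.2690e+02,1.5942e-01,3.6135e-02,1.4199e-02,1.3478e-01,1.0436e-02
1.3417e+02,1.5407e-01,3.4280e-02,1.1843e-02,1.3284e-01,9.3837e-03
1.4187e+02,1.4919e-01,3.2801e-02,9.8756e-03,1.3088e-01,8.4344e-03
1.5000e+02,1.4469e-01,3.1632e-02,8.2325e-03,1.2888e-01,7.5786e-03
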