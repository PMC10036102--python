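energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,3.8841e+02,3.8691e+02,3.8691e+02,1.0768e-01,1.3919e+00
5.2867e+00,3.3414e+02,3.3270e+02,3.3270e+02,1.1114e-01,1.3297e+00
5.5899e+00,2.8721e+02,2.8583e+02,2.8583e+02,1.1445e-01,1.2696e+00
5.9104e+00,2.4653e+02,2.4520e+02,2.4520e+02,1.1763e-01,1.2116e+00
6.2493e+00,2.1145e+02,2.1017e+02,2.1017e+02,1.2068e-01,1.1557e+00
6.6076e+00,1.8124e+02,1.8002e+02,1.8002e+02,1.2360e-01,1.1016e+00
6.9865e+00,1.5526e+02,1.5408e+02,1.5408e+02,1.2641e-01,1.0492e+00
7.3871e+00,1.3291e+02,1.3179e+02,1.3178e+02,1.2912e-01,9.9831e-01
7.8107e+00,1.1371e+02,1.1263e+02,1.1263e+02,1.3174e-01,9.4868e-01
8.2586e+00,9.7230e+01,9.6198e+01,9.6195e+01,1.3427e-01,9.0019e-01
8.7321e+00,8.3087e+01,8.2100e+01,8.2097e+01,1.3672e-01,8.5272e-01
9.2329e+00,7.0934e+01,6.9991e+01,6.9989e+01,1.3909e-01,8.0620e-01
9.7623e+00,6.0522e+01,5.9623e+01,5.9620e+01,1.4139e-01,7.6061e-01
1.0322e+01,5.1618e+01,5.0762e+01,5.0759e+01,1.4361e-01,7.1598e-01
1.0914e+01,4.4009e+01,4.3194e+01,4.3191e+01,1.4574e-01,6.7237e-01
1.1540e+01,3.7508e+01,3.6733e+01,3.6730e+01,1.4778e-01,6.2987e-01
1.2201e+01,3.1957e+01,3.1222e+01,3.1218e+01,1.4973e-01,5.8860e-01
1.2901e+01,2.7197e+01,2.6500e+01,2.6497e+01,1.5157e-01,5.4870e-01
1.3641e+01,2.3142e+01,2.2482e+01,2.2479e+01,1.5329e-01,5.1031e-01
1.4423e+01,1.9690e+01,1.9066e+01,1.9061e+01,1.5489e-01,4.7356e-01
1.5250e+01,1.6752e+01,1.6161e+01,1.6157e+01,1.5636e-01,4.3857e-01
1.6125e+01,1.4252e+01,1.3693e+01,1.3689e+01,1.5770e-01,4.0543e-01
1.7049e+01,1.2126e+01,1.1598e+01,1.1593e+01,1.5890e-01,3.7420e-01
1.8027e+01,1.0318e+01,9.8183e+00,9.8131e+00,1.5996e-01,3.4493e-01
1.9060e+01,8.7816e+00,8.3087e+00,8.3031e+00,1.6087e-01,3.1759e-01
2.0153e+01,7.4762e+00,7.0283e+00,7.0224e+00,1.6165e-01,2.9215e-01
2.1309e+01,6.3674e+00,5.9428e+00,5.9366e+00,1.6229e-01,2.6856e-01
2.2531e+01,5.4259e+00,5.0230e+00,5.0164e+00,1.6280e-01,2.4672e-01
2.3823e+01,4.6267e+00,4.2439e+00,4.2370e+00,1.6317e-01,2.2653e-01
2.5189e+01,3.9484e+00,3.5844e+00,3.5771e+00,1.6343e-01,2.0789e-01
2.6633e+01,3.3730e+00,3.0263e+00,3.0186e+00,1.6356e-01,1.9081e-01
2.8160e+01,2.8828e+00,2.5521e+00,2.5441e+00,1.6358e-01,1.7513e-01
2.9775e+01,2.4675e+00,2.1518e+00,2.1433e+00,1.6349e-01,1.6068e-01
3.1482e+01,2.1157e+00,1.8140e+00,1.8051e+00,1.6330e-01,1.4735e-01
3.3288e+01,1.8178e+00,1.5291e+00,1.5198e+00,1.6301e-01,1.3502e-01
3.5196e+01,1.5654e+00,1.2889e+00,1.2791e+00,1.6262e-01,1.2363e-01
3.7215e+01,1.3515e+00,1.0864e+00,1.0762e+00,1.6215e-01,1.1310e-01
3.9349e+01,1.1702e+00,9.1587e-01,9.0521e-01,1.6158e-01,1.0337e-01
4.1605e+01,1.0164e+00,7.7226e-01,7.6113e-01,1.6093e-01,9.4380e-02
4.3991e+01,8.8605e-01,6.5138e-01,6.3977e-01,1.6020e-01,8.6086e-02
4.6513e+01,7.7540e-01,5.4969e-01,5.3758e-01,1.5938e-01,7.8441e-02
4.9180e+01,6.8145e-01,4.6418e-01,4.5156e-01,1.5849e-01,7.1402e-02
5.2000e+01,6.0163e-01,3.9231e-01,3.7918e-01,1.5752e-01,6.4930e-02
5.4982e+01,5.3376e-01,3.3195e-01,3.1830e-01,1.5647e-01,5.8986e-02
5.8135e+01,4.7599e-01,2.8128e-01,2.6710e-01,1.5535e-01,5.3536e-02
6.1468e+01,4.2677e-01,2.3878e-01,2.2407e-01,1.5416e-01,4.8545e-02
6.4993e+01,3.8479e-01,2.0316e-01,1.8790e-01,1.5291e-01,4.3983e-02
6.8719e+01,3.4892e-01,1.7332e-01,1.5752e-01,1.5158e-01,3.9817e-02
7.2660e+01,3.1822e-01,1.4835e-01,1.3201e-01,1.5020e-01,3.6020e-02
7.6826e+01,2.9190e-01,1.2748e-01,1.1059e-01,1.4875e-01,3.2563e-02
8.1232e+01,2.6927e-01,1.1006e-01,9.2615e-02,1.4724e-01,2.9419e-02
8.5890e+01,2.4978e-01,9.5531e-02,7.7536e-02,1.4568e-01,2.6563e-02
9.0815e+01,2.3292e-01,8.3433e-02,6.4891e-02,1.4406e-01,2.3972e-02
9.6022e+01,2.1831e-01,7.3375e-02,5.4289e-02,1.4239e-01,2.1624e-02
1.0153e+02,2.0558e-01,6.5030e-02,4.5404e-02,1.4068e-01,1.9496e-02
1.0735e+02,1.9445e-01,5.8120e-02,3.7961e-02,1.3892e-01,1.7570e-02
1.1351e+02,1.8467e-01,5.2412e-02,3.1727e-02,1.3711e-01,1.5828e-02
1.2001e+02,1.7603e-01,4.7710e-02,2.6508e-02,1.3527e-01,1.4253e-02
1.2690e+02,1.6836e-01,4.3850e-02,2.2140e-02,1.3339e-01,1.2830e-02
1.3417e+02,1.6151e-01,4.0692e-02,1.8485e-02,1.3148e-01,1.1544e-02
1.4187e+02,1.5535e-01,3.8119e-02,1.5429e-02,1.2954e-01,1.0384e-02
1.5000e+02,1.4977e-01,3.6034e-02,1.2873e-02,1.2756e-01,9.3368e-03
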