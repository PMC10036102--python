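energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,1.8956e+02,1.8834e+02,1.8834e+02,1.0483e-01,1.1152e+00
5.2867e+00,1.6191e+02,1.6073e+02,1.6073e+02,1.0816e-01,1.0692e+00
5.5899e+00,1.3821e+02,1.3708e+02,1.3708e+02,1.1149e-01,1.0229e+00
5.9104e+00,1.1791e+02,1.1682e+02,1.1682e+02,1.1484e-01,9.7624e-01
6.2493e+00,1.0054e+02,9.9492e+01,9.9491e+01,1.1819e-01,9.2937e-01
6.6076e+00,8.5676e+01,8.4674e+01,8.4672e+01,1.2152e-01,8.8239e-01
6.9865e+00,7.2956e+01,7.1997e+01,7.1996e+01,1.2483e-01,8.3549e-01
7.3871e+00,6.2090e+01,6.1175e+01,6.1173e+01,1.2810e-01,7.8887e-01
7.8107e+00,5.2824e+01,5.1952e+01,5.1950e+01,1.3131e-01,7.4278e-01
8.2586e+00,4.4926e+01,4.4096e+01,4.4094e+01,1.3444e-01,6.9747e-01
8.7321e+00,3.8196e+01,3.7408e+01,3.7406e+01,1.3747e-01,6.5319e-01
9.2329e+00,3.2436e+01,3.1687e+01,3.1685e+01,1.4037e-01,6.1021e-01
9.7623e+00,2.7527e+01,2.6817e+01,2.6815e+01,1.4315e-01,5.6874e-01
1.0322e+01,2.3359e+01,2.2687e+01,2.2685e+01,1.4577e-01,5.2900e-01
1.0914e+01,1.9822e+01,1.9186e+01,1.9183e+01,1.4822e-01,4.9112e-01
1.1540e+01,1.6822e+01,1.6219e+01,1.6216e+01,1.5051e-01,4.5523e-01
1.2201e+01,1.4276e+01,1.3706e+01,1.3702e+01,1.5261e-01,4.2138e-01
1.2901e+01,1.2118e+01,1.1578e+01,1.1574e+01,1.5454e-01,3.8959e-01
1.3641e+01,1.0288e+01,9.7762e+00,9.7722e+00,1.5630e-01,3.5984e-01
1.4423e+01,8.7378e+00,8.2520e+00,8.2478e+00,1.5788e-01,3.3208e-01
1.5250e+01,7.4240e+00,6.9630e+00,6.9585e+00,1.5929e-01,3.0622e-01
1.6125e+01,6.3112e+00,5.8732e+00,5.8685e+00,1.6053e-01,2.8219e-01
1.7049e+01,5.3687e+00,4.9522e+00,4.9472e+00,1.6162e-01,2.5987e-01
1.8027e+01,4.5707e+00,4.1743e+00,4.1690e+00,1.6256e-01,2.3918e-01
1.9060e+01,3.8951e+00,3.5174e+00,3.5118e+00,1.6336e-01,2.2000e-01
2.0153e+01,3.3233e+00,2.9629e+00,2.9570e+00,1.6402e-01,2.0226e-01
2.1309e+01,2.8393e+00,2.4952e+00,2.4889e+00,1.6454e-01,1.8586e-01
2.2531e+01,2.4297e+00,2.1007e+00,2.0940e+00,1.6494e-01,1.7073e-01
2.3823e+01,2.0831e+00,1.7681e+00,1.7611e+00,1.6521e-01,1.5680e-01
2.5189e+01,1.7899e+00,1.4879e+00,1.4806e+00,1.6537e-01,1.4398e-01
2.6633e+01,1.5418e+00,1.2520e+00,1.2442e+00,1.6541e-01,1.3212e-01
2.8160e+01,1.3315e+00,1.0532e+00,1.0450e+00,1.6536e-01,1.2111e-01
2.9775e+01,1.1535e+00,8.8599e-01,8.7745e-01,1.6520e-01,1.1090e-01
3.1482e+01,1.0029e+00,7.4543e-01,7.3647e-01,1.6495e-01,1.0144e-01
3.3288e+01,8.7522e-01,6.2732e-01,6.1793e-01,1.6460e-01,9.2685e-02
3.5196e+01,7.6705e-01,5.2812e-01,5.1829e-01,1.6417e-01,8.4594e-02
3.7215e+01,6.7533e-01,4.4485e-01,4.3457e-01,1.6364e-01,7.7125e-02
3.9349e+01,5.9751e-01,3.7499e-01,3.6424e-01,1.6303e-01,7.0239e-02
4.1605e+01,5.3143e-01,3.1642e-01,3.0519e-01,1.6233e-01,6.3902e-02
4.3991e+01,4.7526e-01,2.6734e-01,2.5563e-01,1.6155e-01,5.8077e-02
4.6513e+01,4.2746e-01,2.2625e-01,2.1404e-01,1.6069e-01,5.2732e-02
4.9180e+01,3.8674e-01,1.9187e-01,1.7915e-01,1.5976e-01,4.7835e-02
5.2000e+01,3.5200e-01,1.6313e-01,1.4990e-01,1.5874e-01,4.3357e-02
5.4982e+01,3.2230e-01,1.3914e-01,1.2538e-01,1.5766e-01,3.9266e-02
5.8135e+01,2.9687e-01,1.1912e-01,1.0484e-01,1.5650e-01,3.5536e-02
6.1468e+01,2.7504e-01,1.0245e-01,8.7628e-02,1.5527e-01,3.2138e-02
6.4993e+01,2.5625e-01,8.8582e-02,7.3219e-02,1.5398e-01,2.9048e-02
6.8719e+01,2.4002e-01,7.7066e-02,6.1158e-02,1.5262e-01,2.6239e-02
7.2660e+01,2.2596e-01,6.7523e-02,5.1066e-02,1.5120e-01,2.3690e-02
7.6826e+01,2.1372e-01,5.9631e-02,4.2625e-02,1.4972e-01,2.1378e-02
8.1232e+01,2.0303e-01,5.3124e-02,3.5566e-02,1.4818e-01,1.9282e-02
8.5890e+01,1.9364e-01,4.7774e-02,2.9667e-02,1.4659e-01,1.7384e-02
9.0815e+01,1.8535e-01,4.3393e-02,2.4737e-02,1.4495e-01,1.5667e-02
9.6022e+01,1.7799e-01,3.9821e-02,2.0619e-02,1.4325e-01,1.4113e-02
1.0153e+02,1.7140e-01,3.6923e-02,1.7181e-02,1.4151e-01,1.2707e-02
1.0735e+02,1.6548e-01,3.4588e-02,1.4311e-02,1.3973e-01,1.1438e-02
1.1351e+02,1.6011e-01,3.2721e-02,1.1917e-02,1.3791e-01,1.0291e-02
1.2001e+02,1.5522e-01,3.1242e-02,9.9191e-03,1.3604e-01,9.2554e-03
1.2690e+02,1.5072e-01,3.0086e-02,8.2537e-03,1.3414e-01,8.3211e-03
1.3417e+02,1.4655e-01,2.9195e-02,6.8655e-03,1.3221e-01,7.4784e-03
1.4187e+02,1.4268e-01,2.8524e-02,5.7088e-03,1.3025e-01,6.7187e-03
1.5000e+02,1.3904e-01,2.8032e-02,4.7453e-03,1.2826e-01,6.0341e-03
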