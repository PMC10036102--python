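energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,2.4095e+02,2.3963e+02,2.3963e+02,1.1085e-01,1.2082e+00
5.2867e+00,2.0614e+02,2.0487e+02,2.0487e+02,1.1408e-01,1.1600e+00
5.5899e+00,1.7625e+02,1.7502e+02,1.7502e+02,1.1729e-01,1.1120e+00
5.9104e+00,1.5061e+02,1.4942e+02,1.4942e+02,1.2049e-01,1.0639e+00
6.2493e+00,1.2861e+02,1.2748e+02,1.2748e+02,1.2366e-01,1.0158e+00
6.6076e+00,1.0977e+02,1.0868e+02,1.0868e+02,1.2682e-01,9.6776e-01
6.9865e+00,9.3636e+01,9.2588e+01,9.2586e+01,1.2996e-01,9.1973e-01
7.3871e+00,7.9827e+01,7.8824e+01,7.8822e+01,1.3306e-01,8.7185e-01
7.8107e+00,6.8018e+01,6.7060e+01,6.7058e+01,1.3612e-01,8.2427e-01
8.2586e+00,5.7921e+01,5.7007e+01,5.7005e+01,1.3912e-01,7.7719e-01
8.7321e+00,4.9302e+01,4.8432e+01,4.8429e+01,1.4206e-01,7.3081e-01
9.2329e+00,4.1909e+01,4.1082e+01,4.1079e+01,1.4490e-01,6.8536e-01
9.7623e+00,3.5600e+01,3.4814e+01,3.4812e+01,1.4763e-01,6.4108e-01
1.0322e+01,3.0237e+01,2.9492e+01,2.9489e+01,1.5025e-01,5.9820e-01
1.0914e+01,2.5680e+01,2.4973e+01,2.4970e+01,1.5273e-01,5.5693e-01
1.1540e+01,2.1809e+01,2.1139e+01,2.1136e+01,1.5505e-01,5.1744e-01
1.2201e+01,1.8521e+01,1.7887e+01,1.7884e+01,1.5722e-01,4.7987e-01
1.2901e+01,1.5729e+01,1.5129e+01,1.5126e+01,1.5922e-01,4.4432e-01
1.3641e+01,1.3360e+01,1.2792e+01,1.2788e+01,1.6106e-01,4.1084e-01
1.4423e+01,1.1350e+01,1.0812e+01,1.0807e+01,1.6272e-01,3.7943e-01
1.5250e+01,9.6443e+00,9.1346e+00,9.1300e+00,1.6421e-01,3.5008e-01
1.6125e+01,8.1982e+00,7.7148e+00,7.7099e+00,1.6554e-01,3.2272e-01
1.7049e+01,6.9721e+00,6.5133e+00,6.5082e+00,1.6670e-01,2.9727e-01
1.8027e+01,5.9329e+00,5.4970e+00,5.4915e+00,1.6771e-01,2.7365e-01
1.9060e+01,5.0522e+00,4.6377e+00,4.6319e+00,1.6856e-01,2.5175e-01
2.0153e+01,4.3060e+00,3.9114e+00,3.9052e+00,1.6928e-01,2.3148e-01
2.1309e+01,3.6739e+00,3.2978e+00,3.2913e+00,1.6985e-01,2.1273e-01
2.2531e+01,3.1385e+00,2.7796e+00,2.7728e+00,1.7029e-01,1.9542e-01
2.3823e+01,2.6851e+00,2.3422e+00,2.3350e+00,1.7060e-01,1.7945e-01
2.5189e+01,2.3011e+00,1.9732e+00,1.9656e+00,1.7079e-01,1.6475e-01
2.6633e+01,1.9759e+00,1.6619e+00,1.6539e+00,1.7086e-01,1.5117e-01
2.8160e+01,1.7001e+00,1.3991e+00,1.3907e+00,1.7082e-01,1.3860e-01
2.9775e+01,1.4665e+00,1.1777e+00,1.1689e+00,1.7068e-01,1.2696e-01
3.1482e+01,1.2687e+00,9.9138e-01,9.8212e-01,1.7044e-01,1.1619e-01
3.3288e+01,1.1012e+00,8.3460e-01,8.2490e-01,1.7009e-01,1.0623e-01
3.5196e+01,9.5927e-01,7.0275e-01,6.9259e-01,1.6965e-01,9.7022e-02
3.7215e+01,8.3894e-01,5.9192e-01,5.8129e-01,1.6912e-01,8.8520e-02
3.9349e+01,7.3689e-01,4.9882e-01,4.8771e-01,1.6850e-01,8.0678e-02
4.1605e+01,6.5028e-01,4.2064e-01,4.0904e-01,1.6779e-01,7.3455e-02
4.3991e+01,5.7674e-01,3.5504e-01,3.4293e-01,1.6700e-01,6.6809e-02
4.6513e+01,5.1423e-01,3.0003e-01,2.8741e-01,1.6612e-01,6.0704e-02
4.9180e+01,4.6105e-01,2.5393e-01,2.4078e-01,1.6516e-01,5.5104e-02
5.2000e+01,4.1575e-01,2.1533e-01,2.0165e-01,1.6412e-01,4.9975e-02
5.4982e+01,3.7711e-01,1.8304e-01,1.6882e-01,1.6301e-01,4.5286e-02
5.8135e+01,3.4410e-01,1.5605e-01,1.4128e-01,1.6182e-01,4.1004e-02
6.1468e+01,3.1584e-01,1.3352e-01,1.1819e-01,1.6056e-01,3.7099e-02
6.4993e+01,2.9161e-01,1.1472e-01,9.8837e-02,1.5923e-01,3.3544e-02
6.8719e+01,2.7076e-01,9.9075e-02,8.2624e-02,1.5783e-01,3.0311e-02
7.2660e+01,2.5278e-01,8.6065e-02,6.9046e-02,1.5636e-01,2.7374e-02
7.6826e+01,2.3723e-01,7.5266e-02,5.7678e-02,1.5484e-01,2.4709e-02
8.1232e+01,2.2371e-01,6.6323e-02,4.8165e-02,1.5326e-01,2.2292e-02
8.5890e+01,2.1192e-01,5.8934e-02,4.0206e-02,1.5161e-01,2.0102e-02
9.0815e+01,2.0159e-01,5.2846e-02,3.3551e-02,1.4992e-01,1.8119e-02
9.6022e+01,1.9248e-01,4.7847e-02,2.7987e-02,1.4817e-01,1.6325e-02
1.0153e+02,1.8441e-01,4.3757e-02,2.3337e-02,1.4637e-01,1.4703e-02
1.0735e+02,1.7722e-01,4.0427e-02,1.9454e-02,1.4453e-01,1.3237e-02
1.1351e+02,1.7077e-01,3.7730e-02,1.6210e-02,1.4265e-01,1.1912e-02
1.2001e+02,1.6494e-01,3.5560e-02,1.3503e-02,1.4072e-01,1.0716e-02
1.2690e+02,1.5964e-01,3.3827e-02,1.1244e-02,1.3876e-01,9.6361e-03
1.3417e+02,1.5478e-01,3.2458e-02,9.3595e-03,1.3676e-01,8.6622e-03
1.4187e+02,1.5031e-01,3.1389e-02,7.7883e-03,1.3473e-01,7.7839e-03
1.5000e+02,1.4615e-01,3.0568e-02,6.4785e-03,1.3268e-01,6.9924e-03
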