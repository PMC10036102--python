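energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,1.5456e+02,1.5336e+02,1.5336e+02,1.0442e-01,1.0913e+00
5.2867e+00,1.3177e+02,1.3062e+02,1.3062e+02,1.0828e-01,1.0423e+00
5.5899e+00,1.1228e+02,1.1118e+02,1.1118e+02,1.1216e-01,9.9277e-01
5.9104e+00,9.5580e+01,9.4522e+01,9.4521e+01,1.1604e-01,9.4302e-01
6.2493e+00,8.1322e+01,8.0310e+01,8.0309e+01,1.1991e-01,8.9329e-01
6.6076e+00,6.9166e+01,6.8200e+01,6.8198e+01,1.2373e-01,8.4385e-01
6.9865e+00,5.8806e+01,5.7886e+01,5.7884e+01,1.2748e-01,7.9500e-01
7.3871e+00,4.9982e+01,4.9106e+01,4.9104e+01,1.3114e-01,7.4701e-01
7.8107e+00,4.2469e+01,4.1636e+01,4.1634e+01,1.3469e-01,7.0016e-01
8.2586e+00,3.6076e+01,3.5285e+01,3.5283e+01,1.3811e-01,6.5468e-01
8.7321e+00,3.0637e+01,2.9887e+01,2.9885e+01,1.4137e-01,6.1081e-01
9.2329e+00,2.5990e+01,2.5280e+01,2.5277e+01,1.4447e-01,5.6871e-01
9.7623e+00,2.2038e+01,2.1364e+01,2.1362e+01,1.4739e-01,5.2853e-01
1.0322e+01,1.8686e+01,1.8049e+01,1.8046e+01,1.5012e-01,4.9038e-01
1.0914e+01,1.5846e+01,1.5242e+01,1.5239e+01,1.5266e-01,4.5431e-01
1.1540e+01,1.3439e+01,1.2867e+01,1.2864e+01,1.5501e-01,4.2037e-01
1.2201e+01,1.1400e+01,1.0858e+01,1.0854e+01,1.5716e-01,3.8854e-01
1.2901e+01,9.6734e+00,9.1593e+00,9.1555e+00,1.5911e-01,3.5880e-01
1.3641e+01,8.2115e+00,7.7236e+00,7.7195e+00,1.6088e-01,3.3108e-01
1.4423e+01,6.9740e+00,6.5106e+00,6.5063e+00,1.6246e-01,3.0530e-01
1.5250e+01,5.9268e+00,5.4862e+00,5.4816e+00,1.6387e-01,2.8138e-01
1.6125e+01,5.0408e+00,4.6213e+00,4.6165e+00,1.6510e-01,2.5921e-01
1.7049e+01,4.2912e+00,3.8916e+00,3.8864e+00,1.6618e-01,2.3868e-01
1.8027e+01,3.6573e+00,3.2760e+00,3.2705e+00,1.6710e-01,2.1969e-01
1.9060e+01,3.1211e+00,2.7569e+00,2.7511e+00,1.6787e-01,2.0211e-01
2.0153e+01,2.6677e+00,2.3195e+00,2.3134e+00,1.6851e-01,1.8585e-01
2.1309e+01,2.2843e+00,1.9509e+00,1.9445e+00,1.6901e-01,1.7082e-01
2.2531e+01,1.9601e+00,1.6406e+00,1.6338e+00,1.6938e-01,1.5693e-01
2.3823e+01,1.6859e+00,1.3794e+00,1.3722e+00,1.6964e-01,1.4410e-01
2.5189e+01,1.4541e+00,1.1596e+00,1.1521e+00,1.6978e-01,1.3226e-01
2.6633e+01,1.2579e+00,9.7479e-01,9.6685e-01,1.6980e-01,1.2127e-01
2.8160e+01,1.0919e+00,8.1945e-01,8.1110e-01,1.6973e-01,1.1108e-01
2.9775e+01,9.5139e-01,6.8898e-01,6.8022e-01,1.6955e-01,1.0162e-01
3.1482e+01,8.3242e-01,5.7947e-01,5.7027e-01,1.6928e-01,9.2867e-02
3.3288e+01,7.3163e-01,4.8758e-01,4.7795e-01,1.6891e-01,8.4771e-02
3.5196e+01,6.4618e-01,4.1052e-01,4.0044e-01,1.6845e-01,7.7294e-02
3.7215e+01,5.7368e-01,3.4594e-01,3.3539e-01,1.6789e-01,7.0400e-02
3.9349e+01,5.1212e-01,2.9185e-01,2.8082e-01,1.6725e-01,6.4053e-02
4.1605e+01,4.5979e-01,2.4657e-01,2.3505e-01,1.6652e-01,5.8218e-02
4.3991e+01,4.1525e-01,2.0869e-01,1.9668e-01,1.6571e-01,5.2864e-02
4.6513e+01,3.7729e-01,1.7704e-01,1.6452e-01,1.6482e-01,4.7959e-02
4.9180e+01,3.4489e-01,1.5061e-01,1.3757e-01,1.6385e-01,4.3472e-02
5.2000e+01,3.1717e-01,1.2857e-01,1.1500e-01,1.6280e-01,3.9375e-02
5.4982e+01,2.9341e-01,1.1021e-01,9.6101e-02,1.6167e-01,3.5637e-02
5.8135e+01,2.7299e-01,9.4931e-02,8.0282e-02,1.6048e-01,3.2234e-02
6.1468e+01,2.5539e-01,8.2243e-02,6.7046e-02,1.5921e-01,2.9137e-02
6.4993e+01,2.4017e-01,7.1725e-02,5.5973e-02,1.5788e-01,2.6324e-02
6.8719e+01,2.2696e-01,6.3024e-02,4.6715e-02,1.5648e-01,2.3769e-02
7.2660e+01,2.1544e-01,5.5846e-02,3.8975e-02,1.5501e-01,2.1452e-02
7.6826e+01,2.0535e-01,4.9941e-02,3.2506e-02,1.5349e-01,1.9351e-02
8.1232e+01,1.9646e-01,4.5102e-02,2.7103e-02,1.5191e-01,1.7449e-02
8.5890e+01,1.8859e-01,4.1153e-02,2.2590e-02,1.5027e-01,1.5726e-02
9.0815e+01,1.8157e-01,3.7947e-02,1.8823e-02,1.4858e-01,1.4168e-02
9.6022e+01,1.7528e-01,3.5361e-02,1.5679e-02,1.4684e-01,1.2758e-02
1.0153e+02,1.6960e-01,3.3292e-02,1.3056e-02,1.4506e-01,1.1484e-02
1.0735e+02,1.6443e-01,3.1651e-02,1.0868e-02,1.4322e-01,1.0333e-02
1.1351e+02,1.5969e-01,3.0367e-02,9.0435e-03,1.4135e-01,9.2942e-03
1.2001e+02,1.5532e-01,2.9379e-02,7.5231e-03,1.3944e-01,8.3563e-03
1.2690e+02,1.5125e-01,2.8633e-02,6.2563e-03,1.3749e-01,7.5103e-03
1.3417e+02,1.4745e-01,2.8088e-02,5.2011e-03,1.3550e-01,6.7475e-03
1.4187e+02,1.4387e-01,2.7706e-02,4.3224e-03,1.3349e-01,6.0602e-03
1.5000e+02,1.4048e-01,2.7457e-02,3.5911e-03,1.3145e-01,5.4411e-03
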