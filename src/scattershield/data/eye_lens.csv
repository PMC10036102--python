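energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,3.6778e+01,3.6126e+01,3.6124e+01,1.4017e-01,5.1401e-01
5.2867e+00,3.1151e+01,3.0525e+01,3.0524e+01,1.4479e-01,4.8197e-01
5.5899e+00,2.6378e+01,2.5779e+01,2.5777e+01,1.4916e-01,4.5126e-01
5.9104e+00,2.2333e+01,2.1759e+01,2.1758e+01,1.5330e-01,4.2195e-01
6.2493e+00,1.8907e+01,1.8358e+01,1.8356e+01,1.5719e-01,3.9410e-01
6.6076e+00,1.6006e+01,1.5480e+01,1.5478e+01,1.6083e-01,3.6773e-01
6.9865e+00,1.3552e+01,1.3047e+01,1.3045e+01,1.6421e-01,3.4285e-01
7.1106e+00,1.2858e+01,1.2360e+01,1.2357e+01,1.6520e-01,3.3528e-01
7.1134e+00,1.2842e+01,1.2344e+01,1.2342e+01,1.6522e-01,3.3511e-01
7.3871e+00,1.1476e+01,1.0991e+01,1.0989e+01,1.6736e-01,3.1944e-01
7.8107e+00,9.7198e+00,9.2546e+00,9.2521e+00,1.7027e-01,2.9747e-01
8.2586e+00,8.2358e+00,7.7887e+00,7.7860e+00,1.7295e-01,2.7688e-01
8.7321e+00,6.9820e+00,6.5519e+00,6.5490e+00,1.7540e-01,2.5762e-01
8.9772e+00,6.4329e+00,6.0109e+00,6.0079e+00,1.7652e-01,2.4853e-01
8.9808e+00,6.4253e+00,6.0034e+00,6.0004e+00,1.7653e-01,2.4840e-01
9.2329e+00,5.9218e+00,5.5077e+00,5.5046e+00,1.7765e-01,2.3963e-01
9.7623e+00,5.0270e+00,4.6277e+00,4.6244e+00,1.7970e-01,2.2284e-01
1.0322e+01,4.2703e+00,3.8851e+00,3.8816e+00,1.8155e-01,2.0717e-01
1.0914e+01,3.6318e+00,3.2597e+00,3.2560e+00,1.8323e-01,1.9255e-01
1.1540e+01,3.0941e+00,2.7344e+00,2.7304e+00,1.8473e-01,1.7891e-01
1.2201e+01,2.6414e+00,2.2934e+00,2.2892e+00,1.8608e-01,1.6617e-01
1.2901e+01,2.2603e+00,1.9232e+00,1.9187e+00,1.8727e-01,1.5428e-01
1.3033e+01,2.1977e+00,1.8625e+00,1.8580e+00,1.8746e-01,1.5219e-01
1.3038e+01,2.1952e+00,1.8602e+00,1.8557e+00,1.8747e-01,1.5211e-01
1.3641e+01,1.9393e+00,1.6126e+00,1.6078e+00,1.8832e-01,1.4315e-01
1.4423e+01,1.6690e+00,1.3520e+00,1.3470e+00,1.8924e-01,1.3274e-01
1.5197e+01,1.4543e+00,1.1461e+00,1.1408e+00,1.8998e-01,1.2357e-01
1.5203e+01,1.4528e+00,1.1446e+00,1.1393e+00,1.8998e-01,1.2350e-01
1.5250e+01,1.4412e+00,1.1335e+00,1.1282e+00,1.9003e-01,1.2298e-01
1.5858e+01,1.3033e+00,1.0018e+00,9.9627e-01,1.9050e-01,1.1649e-01
1.5864e+01,1.3019e+00,1.0006e+00,9.9501e-01,1.9050e-01,1.1643e-01
1.6125e+01,1.2492e+00,9.5035e-01,9.4472e-01,1.9070e-01,1.1383e-01
1.7049e+01,1.0874e+00,7.9684e-01,7.9089e-01,1.9124e-01,1.0524e-01
1.8027e+01,9.5082e-01,6.6822e-01,6.6195e-01,1.9168e-01,9.7191e-02
1.9060e+01,8.3554e-01,5.6051e-01,5.5389e-01,1.9201e-01,8.9638e-02
2.0153e+01,7.3815e-01,4.7034e-01,4.6336e-01,1.9223e-01,8.2558e-02
2.1309e+01,6.5581e-01,3.9488e-01,3.8753e-01,1.9235e-01,7.5930e-02
2.2531e+01,5.8613e-01,3.3177e-01,3.2403e-01,1.9236e-01,6.9735e-02
2.3823e+01,5.2711e-01,2.7901e-01,2.7087e-01,1.9228e-01,6.3955e-02
2.5189e+01,4.7705e-01,2.3493e-01,2.2638e-01,1.9210e-01,5.8573e-02
2.6633e+01,4.3453e-01,1.9812e-01,1.8915e-01,1.9182e-01,5.3566e-02
2.8160e+01,3.9810e-01,1.6715e-01,1.5773e-01,1.9145e-01,4.8919e-02
2.9775e+01,3.6712e-01,1.4139e-01,1.3152e-01,1.9098e-01,4.4617e-02
3.1482e+01,3.4073e-01,1.2000e-01,1.0966e-01,1.9043e-01,4.0646e-02
3.3288e+01,3.1819e-01,1.0225e-01,9.1423e-02,1.8978e-01,3.6988e-02
3.5196e+01,2.9890e-01,8.7538e-02,7.6217e-02,1.8905e-01,3.3627e-02
3.7215e+01,2.8232e-01,7.5368e-02,6.3536e-02,1.8823e-01,3.0544e-02
3.9349e+01,2.6802e-01,6.5317e-02,5.2962e-02,1.8733e-01,2.7721e-02
4.1605e+01,2.5564e-01,5.7035e-02,4.4146e-02,1.8635e-01,2.5140e-02
4.3991e+01,2.4487e-01,5.0231e-02,3.6795e-02,1.8529e-01,2.2783e-02
4.6513e+01,2.3545e-01,4.4661e-02,3.0666e-02,1.8415e-01,2.0633e-02
4.9180e+01,2.2717e-01,4.0120e-02,2.5557e-02,1.8294e-01,1.8674e-02
5.2000e+01,2.1983e-01,3.6440e-02,2.1297e-02,1.8165e-01,1.6890e-02
5.4982e+01,2.1330e-01,3.3477e-02,1.7747e-02,1.8029e-01,1.5268e-02
5.8135e+01,2.0743e-01,3.1114e-02,1.4787e-02,1.7885e-01,1.3793e-02
6.1468e+01,2.0213e-01,2.9250e-02,1.2321e-02,1.7735e-01,1.2453e-02
6.4993e+01,1.9729e-01,2.7803e-02,1.0265e-02,1.7579e-01,1.1237e-02
6.8719e+01,1.9284e-01,2.6704e-02,8.5513e-03,1.7416e-01,1.0134e-02
7.2660e+01,1.8872e-01,2.5894e-02,7.1235e-03,1.7247e-01,9.1349e-03
7.6826e+01,1.8487e-01,2.5325e-02,5.9337e-03,1.7071e-01,8.2295e-03
8.1232e+01,1.8125e-01,2.4954e-02,4.9423e-03,1.6890e-01,7.4102e-03
8.5890e+01,1.7782e-01,2.4749e-02,4.1163e-03,1.6703e-01,6.6691e-03
8.7987e+01,1.7637e-01,2.4717e-02,3.8030e-03,1.6620e-01,6.3706e-03
8.8022e+01,1.7635e-01,2.4717e-02,3.7980e-03,1.6618e-01,6.3657e-03
9.0815e+01,1.7454e-01,2.4679e-02,3.4281e-03,1.6511e-01,5.9993e-03
9.6022e+01,1.7139e-01,2.4721e-02,2.8548e-03,1.6314e-01,5.3944e-03
1.0153e+02,1.6834e-01,2.4854e-02,2.3772e-03,1.6112e-01,4.8484e-03
1.0735e+02,1.6539e-01,2.5060e-02,1.9794e-03,1.5905e-01,4.3560e-03
1.1351e+02,1.6250e-01,2.5324e-02,1.6481e-03,1.5694e-01,3.9121e-03
1.2001e+02,1.5967e-01,2.5634e-02,1.3721e-03,1.5479e-01,3.5122e-03
1.2690e+02,1.5690e-01,2.5979e-02,1.1422e-03,1.5260e-01,3.1521e-03
1.3417e+02,1.5416e-01,2.6350e-02,9.5085e-04,1.5038e-01,2.8281e-03
1.4187e+02,1.5146e-01,2.6739e-02,7.9146e-04,1.4813e-01,2.5367e-03
1.5000e+02,1.4878e-01,2.7139e-02,6.5876e-04,1.4585e-01,2.2748e-03
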