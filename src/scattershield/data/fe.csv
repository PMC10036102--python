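energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,1.3476e+02,1.3225e+02,1.3225e+02,9.1235e-02,2.4202e+00
5.2867e+00,1.1573e+02,1.1332e+02,1.1332e+02,9.5222e-02,2.3110e+00
5.5899e+00,9.9372e+01,9.7071e+01,9.7070e+01,9.9184e-02,2.2020e+00
5.9104e+00,8.5321e+01,8.3125e+01,8.3124e+01,1.0310e-01,2.0938e+00
6.2493e+00,7.3252e+01,7.1160e+01,7.1158e+01,1.0695e-01,1.9869e+00
6.6076e+00,6.2887e+01,6.0896e+01,6.0895e+01,1.1071e-01,1.8819e+00
6.9865e+00,5.3988e+01,5.2096e+01,5.2094e+01,1.1437e-01,1.7793e+00
7.1106e+00,5.1449e+01,4.9587e+01,4.9586e+01,1.1549e-01,1.7475e+00
7.1134e+00,4.2030e+02,4.1844e+02,4.1844e+02,1.1552e-01,1.7468e+00
7.3871e+00,3.7559e+02,3.7380e+02,3.7380e+02,1.1790e-01,1.6795e+00
7.8107e+00,3.2494e+02,3.2324e+02,3.2324e+02,1.2129e-01,1.5829e+00
8.2586e+00,2.8165e+02,2.8003e+02,2.8003e+02,1.2452e-01,1.4900e+00
8.7321e+00,2.4364e+02,2.4211e+02,2.4211e+02,1.2760e-01,1.4008e+00
9.2329e+00,2.1033e+02,2.0888e+02,2.0888e+02,1.3050e-01,1.3158e+00
9.7623e+00,1.8145e+02,1.8009e+02,1.8009e+02,1.3322e-01,1.2350e+00
1.0322e+01,1.5643e+02,1.5514e+02,1.5514e+02,1.3576e-01,1.1585e+00
1.0914e+01,1.3477e+02,1.3355e+02,1.3355e+02,1.3812e-01,1.0861e+00
1.1540e+01,1.1603e+02,1.1487e+02,1.1487e+02,1.4031e-01,1.0180e+00
1.2201e+01,9.9823e+01,9.8730e+01,9.8727e+01,1.4232e-01,9.5371e-01
1.2901e+01,8.5824e+01,8.4790e+01,8.4786e+01,1.4418e-01,8.9316e-01
1.3641e+01,7.3738e+01,7.2759e+01,7.2756e+01,1.4588e-01,8.3605e-01
1.4423e+01,6.3297e+01,6.2372e+01,6.2368e+01,1.4743e-01,7.8209e-01
1.5250e+01,5.4270e+01,5.3395e+01,5.3391e+01,1.4885e-01,7.3103e-01
1.6125e+01,4.6509e+01,4.5681e+01,4.5676e+01,1.5014e-01,6.8260e-01
1.7049e+01,3.9838e+01,3.9055e+01,3.9050e+01,1.5131e-01,6.3660e-01
1.8027e+01,3.4110e+01,3.3370e+01,3.3365e+01,1.5237e-01,5.9285e-01
1.9060e+01,2.9194e+01,2.8495e+01,2.8489e+01,1.5331e-01,5.5121e-01
2.0153e+01,2.4977e+01,2.4317e+01,2.4311e+01,1.5415e-01,5.1160e-01
2.1309e+01,2.1361e+01,2.0738e+01,2.0732e+01,1.5487e-01,4.7394e-01
2.2531e+01,1.8263e+01,1.7676e+01,1.7669e+01,1.5549e-01,4.3819e-01
2.3823e+01,1.5610e+01,1.5056e+01,1.5049e+01,1.5601e-01,4.0435e-01
2.5189e+01,1.3338e+01,1.2816e+01,1.2809e+01,1.5641e-01,3.7247e-01
2.6633e+01,1.1396e+01,1.0903e+01,1.0896e+01,1.5667e-01,3.4361e-01
2.8160e+01,9.7328e+00,9.2661e+00,9.2584e+00,1.5679e-01,3.1761e-01
2.9775e+01,8.3138e+00,7.8712e+00,7.8631e+00,1.5678e-01,2.9397e-01
3.1482e+01,7.1004e+00,6.6799e+00,6.6714e+00,1.5667e-01,2.7232e-01
3.3288e+01,6.0623e+00,5.6623e+00,5.6534e+00,1.5645e-01,2.5239e-01
3.5196e+01,5.1795e+00,4.7987e+00,4.7894e+00,1.5614e-01,2.3397e-01
3.7215e+01,4.4288e+00,4.0660e+00,4.0562e+00,1.5574e-01,2.1691e-01
3.9349e+01,3.7905e+00,3.4444e+00,3.4342e+00,1.5524e-01,2.0107e-01
4.1605e+01,3.2477e+00,2.9174e+00,2.9067e+00,1.5467e-01,1.8633e-01
4.3991e+01,2.7862e+00,2.4707e+00,2.4595e+00,1.5401e-01,1.7261e-01
4.6513e+01,2.3936e+00,2.0922e+00,2.0805e+00,1.5328e-01,1.5982e-01
4.9180e+01,2.0597e+00,1.7715e+00,1.7594e+00,1.5247e-01,1.4788e-01
5.2000e+01,1.7757e+00,1.5000e+00,1.4873e+00,1.5159e-01,1.3673e-01
5.4982e+01,1.5339e+00,1.2701e+00,1.2570e+00,1.5063e-01,1.2632e-01
5.8135e+01,1.3282e+00,1.0756e+00,1.0620e+00,1.4961e-01,1.1658e-01
6.1468e+01,1.1529e+00,9.1113e-01,8.9696e-01,1.4851e-01,1.0747e-01
6.4993e+01,1.0037e+00,7.7205e-01,7.5734e-01,1.4735e-01,9.8963e-02
6.8719e+01,8.7641e-01,6.5449e-01,6.3926e-01,1.4613e-01,9.1014e-02
7.2660e+01,7.6787e-01,5.5519e-01,5.3942e-01,1.4485e-01,8.3595e-02
7.6826e+01,6.7522e-01,4.7134e-01,4.5504e-01,1.4350e-01,7.6679e-02
8.1232e+01,5.9607e-01,4.0057e-01,3.8373e-01,1.4210e-01,7.0241e-02
8.5890e+01,5.2839e-01,3.4087e-01,3.2350e-01,1.4064e-01,6.4259e-02
9.0815e+01,4.7047e-01,2.9054e-01,2.7264e-01,1.3912e-01,5.8711e-02
9.6022e+01,4.2083e-01,2.4813e-01,2.2970e-01,1.3756e-01,5.3575e-02
1.0153e+02,3.7823e-01,2.1243e-01,1.9346e-01,1.3594e-01,4.8832e-02
1.0735e+02,3.4163e-01,1.8238e-01,1.6289e-01,1.3428e-01,4.4460e-02
1.1351e+02,3.1012e-01,1.5711e-01,1.3711e-01,1.3257e-01,4.0439e-02
1.2001e+02,2.8294e-01,1.3587e-01,1.1537e-01,1.3083e-01,3.6747e-02
1.2690e+02,2.5945e-01,1.1805e-01,9.7044e-02,1.2904e-01,3.3363e-02
1.3417e+02,2.3910e-01,1.0309e-01,8.1606e-02,1.2722e-01,3.0267e-02
1.4187e+02,2.2141e-01,9.0563e-02,6.8602e-02,1.2537e-01,2.7438e-02
1.5000e+02,2.0600e-01,8.0073e-02,5.7652e-02,1.2349e-01,2.4857e-02
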