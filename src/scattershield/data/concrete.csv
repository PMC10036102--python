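energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,1.4926e+02,1.4823e+02,1.4823e+02,1.1689e-01,9.2183e-01
5.2867e+00,1.2776e+02,1.2676e+02,1.2676e+02,1.2093e-01,8.7661e-01
5.5899e+00,1.0929e+02,1.0833e+02,1.0833e+02,1.2485e-01,8.3229e-01
5.9104e+00,9.3438e+01,9.2522e+01,9.2520e+01,1.2864e-01,7.8897e-01
6.2493e+00,7.9842e+01,7.8965e+01,7.8963e+01,1.3230e-01,7.4669e-01
6.6076e+00,6.8189e+01,6.7349e+01,6.7347e+01,1.3580e-01,7.0553e-01
6.9865e+00,5.8206e+01,5.7403e+01,5.7401e+01,1.3916e-01,6.6555e-01
7.1106e+00,5.5358e+01,5.4567e+01,5.4565e+01,1.4016e-01,6.5306e-01
7.1134e+00,6.0460e+01,5.9669e+01,5.9667e+01,1.4019e-01,6.5278e-01
7.3871e+00,5.4268e+01,5.3501e+01,5.3499e+01,1.4236e-01,6.2679e-01
7.8107e+00,4.6339e+01,4.5607e+01,4.5604e+01,1.4541e-01,5.8932e-01
8.2586e+00,3.9559e+01,3.8860e+01,3.8858e+01,1.4830e-01,5.5317e-01
8.7321e+00,3.3754e+01,3.3087e+01,3.3085e+01,1.5102e-01,5.1839e-01
8.9772e+00,3.1179e+01,3.0527e+01,3.0525e+01,1.5229e-01,5.0155e-01
8.9808e+00,3.1143e+01,3.0492e+01,3.0489e+01,1.5231e-01,5.0131e-01
9.2329e+00,2.8769e+01,2.8133e+01,2.8130e+01,1.5359e-01,4.8503e-01
9.7623e+00,2.4508e+01,2.3901e+01,2.3899e+01,1.5598e-01,4.5313e-01
1.0322e+01,2.0874e+01,2.0296e+01,2.0293e+01,1.5822e-01,4.2271e-01
1.0914e+01,1.7778e+01,1.7227e+01,1.7224e+01,1.6029e-01,3.9379e-01
1.1540e+01,1.5141e+01,1.4616e+01,1.4613e+01,1.6219e-01,3.6637e-01
1.2201e+01,1.2897e+01,1.2396e+01,1.2392e+01,1.6393e-01,3.4046e-01
1.2901e+01,1.0987e+01,1.0509e+01,1.0505e+01,1.6552e-01,3.1603e-01
1.3033e+01,1.0671e+01,1.0197e+01,1.0193e+01,1.6578e-01,3.1171e-01
1.3038e+01,1.0658e+01,1.0185e+01,1.0181e+01,1.6579e-01,3.1154e-01
1.3641e+01,9.3613e+00,8.9055e+00,8.9013e+00,1.6695e-01,2.9303e-01
1.4423e+01,7.9787e+00,7.5435e+00,7.5390e+00,1.6824e-01,2.7144e-01
1.5197e+01,6.8706e+00,6.4536e+00,6.4489e+00,1.6931e-01,2.5241e-01
1.5203e+01,6.8628e+00,6.4459e+00,6.4412e+00,1.6932e-01,2.5227e-01
1.5250e+01,6.8026e+00,6.3868e+00,6.3820e+00,1.6938e-01,2.5118e-01
1.5858e+01,6.0849e+00,5.6821e+00,5.6771e+00,1.7008e-01,2.3774e-01
1.5864e+01,6.0780e+00,5.6753e+00,5.6703e+00,1.7009e-01,2.3760e-01
1.6125e+01,5.8028e+00,5.4053e+00,5.4002e+00,1.7038e-01,2.3221e-01
1.7049e+01,4.9532e+00,4.5728e+00,4.5675e+00,1.7125e-01,2.1447e-01
1.8027e+01,4.2312e+00,3.8670e+00,3.8614e+00,1.7199e-01,1.9788e-01
1.9060e+01,3.6179e+00,3.2689e+00,3.2629e+00,1.7260e-01,1.8240e-01
2.0153e+01,3.0973e+00,2.7625e+00,2.7562e+00,1.7310e-01,1.6796e-01
2.1309e+01,2.6552e+00,2.3339e+00,2.3272e+00,1.7347e-01,1.5452e-01
2.2531e+01,2.2800e+00,1.9712e+00,1.9642e+00,1.7374e-01,1.4202e-01
2.3823e+01,1.9615e+00,1.6646e+00,1.6572e+00,1.7389e-01,1.3043e-01
2.5189e+01,1.6913e+00,1.4054e+00,1.3976e+00,1.7394e-01,1.1969e-01
2.6633e+01,1.4619e+00,1.1864e+00,1.1782e+00,1.7388e-01,1.0977e-01
2.8160e+01,1.2663e+00,1.0005e+00,9.9200e-01,1.7372e-01,1.0061e-01
2.9775e+01,1.1005e+00,8.4390e-01,8.3493e-01,1.7346e-01,9.2137e-02
3.1482e+01,9.5990e-01,7.1188e-01,7.0248e-01,1.7311e-01,8.4308e-02
3.3288e+01,8.4055e-01,6.0066e-01,5.9081e-01,1.7267e-01,7.7077e-02
3.5196e+01,7.3929e-01,5.0706e-01,4.9675e-01,1.7213e-01,7.0403e-02
3.7215e+01,6.5332e-01,4.2834e-01,4.1756e-01,1.7151e-01,6.4250e-02
3.9349e+01,5.8028e-01,3.6216e-01,3.5090e-01,1.7080e-01,5.8582e-02
4.1605e+01,5.1817e-01,3.0655e-01,2.9479e-01,1.7001e-01,5.3368e-02
4.3991e+01,4.6531e-01,2.5986e-01,2.4759e-01,1.6914e-01,4.8576e-02
4.6513e+01,4.2026e-01,2.2068e-01,2.0789e-01,1.6819e-01,4.4177e-02
4.9180e+01,3.8182e-01,1.8782e-01,1.7451e-01,1.6716e-01,4.0143e-02
5.2000e+01,3.4896e-01,1.6029e-01,1.4645e-01,1.6606e-01,3.6448e-02
5.4982e+01,3.2082e-01,1.3725e-01,1.2287e-01,1.6488e-01,3.3068e-02
5.8135e+01,2.9667e-01,1.1799e-01,1.0305e-01,1.6364e-01,2.9979e-02
6.1468e+01,2.7589e-01,1.0190e-01,8.6408e-02,1.6233e-01,2.7160e-02
6.4993e+01,2.5797e-01,8.8491e-02,7.2433e-02,1.6094e-01,2.4588e-02
6.8719e+01,2.4245e-01,7.7327e-02,6.0702e-02,1.5950e-01,2.2245e-02
7.2660e+01,2.2896e-01,6.8052e-02,5.0856e-02,1.5799e-01,2.0113e-02
7.6826e+01,2.1720e-01,6.0364e-02,4.2596e-02,1.5643e-01,1.8174e-02
8.1232e+01,2.0688e-01,5.4009e-02,3.5667e-02,1.5480e-01,1.6413e-02
8.5890e+01,1.9780e-01,4.8772e-02,2.9857e-02,1.5312e-01,1.4814e-02
8.7987e+01,1.9418e-01,4.6845e-02,2.7643e-02,1.5237e-01,1.4168e-02
8.8022e+01,1.9413e-01,4.6814e-02,2.7607e-02,1.5236e-01,1.4158e-02
9.0815e+01,1.8974e-01,4.4472e-02,2.4987e-02,1.5139e-01,1.3364e-02
9.6022e+01,1.8257e-01,4.0958e-02,2.0905e-02,1.4961e-01,1.2050e-02
1.0153e+02,1.7613e-01,3.8102e-02,1.7485e-02,1.4778e-01,1.0860e-02
1.0735e+02,1.7031e-01,3.5794e-02,1.4621e-02,1.4591e-01,9.7826e-03
1.1351e+02,1.6503e-01,3.3945e-02,1.2222e-02,1.4399e-01,8.8086e-03
1.2001e+02,1.6018e-01,3.2478e-02,1.0214e-02,1.4204e-01,7.9282e-03
1.2690e+02,1.5572e-01,3.1328e-02,8.5341e-03,1.4005e-01,7.1329e-03
1.3417e+02,1.5157e-01,3.0440e-02,7.1282e-03,1.3802e-01,6.4150e-03
1.4187e+02,1.4769e-01,2.9770e-02,5.9524e-03,1.3597e-01,5.7673e-03
1.5000e+02,1.4404e-01,2.9278e-02,4.9691e-03,1.3389e-01,5.1832e-03
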