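energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,4.5922e+01,4.5185e+01,4.5184e+01,1.2015e-01,6.1817e-01
5.2867e+00,3.8877e+01,3.8174e+01,3.8173e+01,1.2471e-01,5.7965e-01
5.5899e+00,3.2905e+01,3.2234e+01,3.2233e+01,1.2907e-01,5.4259e-01
5.9104e+00,2.7843e+01,2.7205e+01,2.7203e+01,1.3323e-01,5.0712e-01
6.2493e+00,2.3557e+01,2.2948e+01,2.2946e+01,1.3716e-01,4.7333e-01
6.6076e+00,1.9928e+01,1.9348e+01,1.9346e+01,1.4087e-01,4.4127e-01
6.9865e+00,1.6857e+01,1.6304e+01,1.6302e+01,1.4434e-01,4.1097e-01
7.3871e+00,1.4260e+01,1.3732e+01,1.3729e+01,1.4758e-01,3.8244e-01
7.8107e+00,1.2063e+01,1.1559e+01,1.1557e+01,1.5059e-01,3.5565e-01
8.2586e+00,1.0207e+01,9.7259e+00,9.7235e+00,1.5337e-01,3.3056e-01
8.7321e+00,8.6396e+00,8.1791e+00,8.1765e+00,1.5593e-01,3.0711e-01
9.2329e+00,7.3151e+00,6.8744e+00,6.8716e+00,1.5828e-01,2.8523e-01
9.7623e+00,6.1977e+00,5.7753e+00,5.7724e+00,1.6043e-01,2.6484e-01
1.0322e+01,5.2523e+00,4.8472e+00,4.8440e+00,1.6239e-01,2.4587e-01
1.0914e+01,4.4543e+00,4.0653e+00,4.0619e+00,1.6416e-01,2.2823e-01
1.1540e+01,3.7828e+00,3.4088e+00,3.4052e+00,1.6575e-01,2.1183e-01
1.2201e+01,3.2177e+00,2.8578e+00,2.8540e+00,1.6718e-01,1.9657e-01
1.2901e+01,2.7422e+00,2.3954e+00,2.3914e+00,1.6846e-01,1.8237e-01
1.3641e+01,2.3420e+00,2.0075e+00,2.0033e+00,1.6959e-01,1.6914e-01
1.4423e+01,2.0051e+00,1.6823e+00,1.6777e+00,1.7059e-01,1.5680e-01
1.5250e+01,1.7215e+00,1.4096e+00,1.4048e+00,1.7146e-01,1.4527e-01
1.6125e+01,1.4826e+00,1.1810e+00,1.1759e+00,1.7221e-01,1.3450e-01
1.7049e+01,1.2814e+00,9.8948e-01,9.8411e-01,1.7284e-01,1.2440e-01
1.8027e+01,1.1117e+00,8.2906e-01,8.2338e-01,1.7336e-01,1.1495e-01
1.9060e+01,9.6860e-01,6.9473e-01,6.8874e-01,1.7378e-01,1.0609e-01
2.0153e+01,8.4785e-01,5.8229e-01,5.7597e-01,1.7409e-01,9.7784e-02
2.1309e+01,7.4586e-01,4.8821e-01,4.8155e-01,1.7431e-01,9.0005e-02
2.2531e+01,6.5965e-01,4.0952e-01,4.0250e-01,1.7443e-01,8.2725e-02
2.3823e+01,5.8672e-01,3.4373e-01,3.3635e-01,1.7445e-01,7.5923e-02
2.5189e+01,5.2496e-01,2.8876e-01,2.8101e-01,1.7438e-01,6.9580e-02
2.6633e+01,4.7259e-01,2.4286e-01,2.3471e-01,1.7421e-01,6.3669e-02
2.8160e+01,4.2778e-01,2.0421e-01,1.9565e-01,1.7396e-01,5.8174e-02
2.9775e+01,3.8977e-01,1.7204e-01,1.6307e-01,1.7362e-01,5.3082e-02
3.1482e+01,3.5747e-01,1.4531e-01,1.3591e-01,1.7318e-01,4.8376e-02
3.3288e+01,3.2997e-01,1.2311e-01,1.1326e-01,1.7267e-01,4.4037e-02
3.5196e+01,3.0650e-01,1.0469e-01,9.4387e-02,1.7207e-01,4.0046e-02
3.7215e+01,2.8642e-01,8.9424e-02,7.8652e-02,1.7138e-01,3.6384e-02
3.9349e+01,2.6918e-01,7.6789e-02,6.5538e-02,1.7061e-01,3.3028e-02
4.1605e+01,2.5434e-01,6.6349e-02,5.4607e-02,1.6977e-01,2.9959e-02
4.3991e+01,2.4150e-01,5.7741e-02,4.5497e-02,1.6885e-01,2.7156e-02
4.6513e+01,2.3035e-01,5.0660e-02,3.7905e-02,1.6785e-01,2.4598e-02
4.9180e+01,2.2063e-01,4.4855e-02,3.1578e-02,1.6678e-01,2.2267e-02
5.2000e+01,2.1209e-01,4.0113e-02,2.6306e-02,1.6564e-01,2.0145e-02
5.4982e+01,2.0456e-01,3.6259e-02,2.1912e-02,1.6443e-01,1.8214e-02
5.8135e+01,1.9786e-01,3.3145e-02,1.8252e-02,1.6315e-01,1.6459e-02
6.1468e+01,1.9188e-01,3.0648e-02,1.5202e-02,1.6181e-01,1.4864e-02
6.4993e+01,1.8648e-01,2.8665e-02,1.2661e-02,1.6041e-01,1.3416e-02
6.8719e+01,1.8159e-01,2.7111e-02,1.0545e-02,1.5894e-01,1.2103e-02
7.2660e+01,1.7711e-01,2.5914e-02,8.7813e-03,1.5741e-01,1.0912e-02
7.6826e+01,1.7298e-01,2.5013e-02,7.3124e-03,1.5583e-01,9.8332e-03
8.1232e+01,1.6914e-01,2.4358e-02,6.0890e-03,1.5419e-01,8.8564e-03
8.5890e+01,1.6555e-01,2.3908e-02,5.0699e-03,1.5250e-01,7.9726e-03
9.0815e+01,1.6216e-01,2.3626e-02,4.2212e-03,1.5076e-01,7.1736e-03
9.6022e+01,1.5894e-01,2.3482e-02,3.5144e-03,1.4897e-01,6.4517e-03
1.0153e+02,1.5586e-01,2.3452e-02,2.9257e-03,1.4714e-01,5.7999e-03
1.0735e+02,1.5291e-01,2.3515e-02,2.4356e-03,1.4526e-01,5.2118e-03
1.1351e+02,1.5005e-01,2.3652e-02,2.0274e-03,1.4334e-01,4.6815e-03
1.2001e+02,1.4728e-01,2.3849e-02,1.6876e-03,1.4139e-01,4.2036e-03
1.2690e+02,1.4457e-01,2.4092e-02,1.4046e-03,1.3940e-01,3.7733e-03
1.3417e+02,1.4193e-01,2.4371e-02,1.1690e-03,1.3737e-01,3.3859e-03
1.4187e+02,1.3933e-01,2.4677e-02,9.7291e-04,1.3532e-01,3.0374e-03
1.5000e+02,1.3678e-01,2.5001e-02,8.0965e-04,1.3324e-01,2.7240e-03
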