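energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,4.0622e+01,3.9951e+01,3.9949e+01,1.4002e-01,5.3292e-01
5.2867e+00,3.4446e+01,3.3803e+01,3.3801e+01,1.4471e-01,4.9985e-01
5.5899e+00,2.9201e+01,2.8585e+01,2.8584e+01,1.4917e-01,4.6811e-01
5.9104e+00,2.4750e+01,2.4161e+01,2.4159e+01,1.5339e-01,4.3779e-01
6.2493e+00,2.0975e+01,2.0411e+01,2.0409e+01,1.5735e-01,4.0895e-01
6.6076e+00,1.7775e+01,1.7234e+01,1.7232e+01,1.6107e-01,3.8163e-01
6.9865e+00,1.5063e+01,1.4544e+01,1.4542e+01,1.6453e-01,3.5583e-01
7.1106e+00,1.4295e+01,1.3784e+01,1.3781e+01,1.6554e-01,3.4797e-01
7.1134e+00,1.4278e+01,1.3767e+01,1.3765e+01,1.6556e-01,3.4779e-01
7.3871e+00,1.2765e+01,1.2268e+01,1.2266e+01,1.6775e-01,3.3153e-01
7.8107e+00,1.0820e+01,1.0343e+01,1.0341e+01,1.7072e-01,3.0871e-01
8.2586e+00,9.1741e+00,8.7161e+00,8.7134e+00,1.7346e-01,2.8731e-01
8.7321e+00,7.7816e+00,7.3412e+00,7.3383e+00,1.7598e-01,2.6729e-01
8.9772e+00,7.1713e+00,6.7393e+00,6.7363e+00,1.7712e-01,2.5783e-01
8.9808e+00,7.1628e+00,6.7310e+00,6.7280e+00,1.7713e-01,2.5770e-01
9.2329e+00,6.6029e+00,6.1791e+00,6.1760e+00,1.7828e-01,2.4858e-01
9.7623e+00,5.6066e+00,5.1984e+00,5.1951e+00,1.8037e-01,2.3111e-01
1.0322e+01,4.7633e+00,4.3698e+00,4.3662e+00,1.8227e-01,2.1481e-01
1.0914e+01,4.0508e+00,3.6709e+00,3.6672e+00,1.8399e-01,1.9960e-01
1.1540e+01,3.4501e+00,3.0832e+00,3.0792e+00,1.8553e-01,1.8542e-01
1.2201e+01,2.9439e+00,2.5891e+00,2.5848e+00,1.8690e-01,1.7218e-01
1.2901e+01,2.5172e+00,2.1737e+00,2.1692e+00,1.8812e-01,1.5982e-01
1.3033e+01,2.4470e+00,2.1056e+00,2.1011e+00,1.8832e-01,1.5766e-01
1.3038e+01,2.4443e+00,2.1030e+00,2.0984e+00,1.8833e-01,1.5757e-01
1.3641e+01,2.1574e+00,1.8248e+00,1.8200e+00,1.8920e-01,1.4827e-01
1.4423e+01,1.8542e+00,1.5316e+00,1.5266e+00,1.9013e-01,1.3746e-01
1.5197e+01,1.6132e+00,1.2997e+00,1.2943e+00,1.9089e-01,1.2795e-01
1.5203e+01,1.6115e+00,1.2981e+00,1.2927e+00,1.9089e-01,1.2788e-01
1.5250e+01,1.5984e+00,1.2855e+00,1.2802e+00,1.9094e-01,1.2734e-01
1.5858e+01,1.4434e+00,1.1370e+00,1.1314e+00,1.9141e-01,1.2062e-01
1.5864e+01,1.4419e+00,1.1356e+00,1.1300e+00,1.9142e-01,1.2056e-01
1.6125e+01,1.3827e+00,1.0789e+00,1.0732e+00,1.9162e-01,1.1786e-01
1.7049e+01,1.2006e+00,9.0547e-01,8.9950e-01,1.9218e-01,1.0897e-01
1.8027e+01,1.0470e+00,7.6001e-01,7.5370e-01,1.9262e-01,1.0063e-01
1.9060e+01,9.1715e-01,6.3803e-01,6.3138e-01,1.9296e-01,9.2820e-02
2.0153e+01,8.0745e-01,5.3579e-01,5.2877e-01,1.9318e-01,8.5497e-02
2.1309e+01,7.1468e-01,4.5012e-01,4.4273e-01,1.9331e-01,7.8643e-02
2.2531e+01,6.3616e-01,3.7837e-01,3.7060e-01,1.9333e-01,7.2238e-02
2.3823e+01,5.6964e-01,3.1831e-01,3.1013e-01,1.9324e-01,6.6261e-02
2.5189e+01,5.1323e-01,2.6806e-01,2.5947e-01,1.9306e-01,6.0697e-02
2.6633e+01,4.6533e-01,2.2605e-01,2.1703e-01,1.9279e-01,5.5520e-02
2.8160e+01,4.2431e-01,1.9064e-01,1.8118e-01,1.9242e-01,5.0715e-02
2.9775e+01,3.8945e-01,1.6115e-01,1.5123e-01,1.9195e-01,4.6266e-02
3.1482e+01,3.5978e-01,1.3662e-01,1.2622e-01,1.9140e-01,4.2159e-02
3.3288e+01,3.3447e-01,1.1623e-01,1.0535e-01,1.9075e-01,3.8375e-02
3.5196e+01,3.1283e-01,9.9293e-02,8.7914e-02,1.9002e-01,3.4897e-02
3.7215e+01,2.9427e-01,8.5254e-02,7.3362e-02,1.8920e-01,3.1705e-02
3.9349e+01,2.7829e-01,7.3631e-02,6.1214e-02,1.8830e-01,2.8782e-02
4.1605e+01,2.6449e-01,6.4029e-02,5.1074e-02,1.8731e-01,2.6108e-02
4.3991e+01,2.5252e-01,5.6115e-02,4.2610e-02,1.8624e-01,2.3665e-02
4.6513e+01,2.4208e-01,4.9613e-02,3.5546e-02,1.8510e-01,2.1437e-02
4.9180e+01,2.3294e-01,4.4290e-02,2.9651e-02,1.8388e-01,1.9406e-02
5.2000e+01,2.2487e-01,3.9953e-02,2.4732e-02,1.8259e-01,1.7556e-02
5.4982e+01,2.1772e-01,3.6439e-02,2.0627e-02,1.8122e-01,1.5873e-02
5.8135e+01,2.1132e-01,3.3613e-02,1.7202e-02,1.7978e-01,1.4342e-02
6.1468e+01,2.0557e-01,3.1362e-02,1.4345e-02,1.7827e-01,1.2952e-02
6.4993e+01,2.0035e-01,2.9591e-02,1.1961e-02,1.7670e-01,1.1689e-02
6.8719e+01,1.9558e-01,2.8220e-02,9.9729e-03,1.7506e-01,1.0544e-02
7.2660e+01,1.9118e-01,2.7183e-02,8.3143e-03,1.7336e-01,9.5059e-03
7.6826e+01,1.8709e-01,2.6423e-02,6.9310e-03,1.7160e-01,8.5653e-03
8.1232e+01,1.8327e-01,2.5893e-02,5.7774e-03,1.6978e-01,7.7139e-03
8.5890e+01,1.7966e-01,2.5555e-02,4.8153e-03,1.6790e-01,6.9436e-03
8.7987e+01,1.7815e-01,2.5474e-02,4.4502e-03,1.6706e-01,6.6333e-03
8.8022e+01,1.7812e-01,2.5473e-02,4.4444e-03,1.6705e-01,6.6282e-03
9.0815e+01,1.7623e-01,2.5375e-02,4.0131e-03,1.6597e-01,6.2473e-03
9.6022e+01,1.7295e-01,2.5325e-02,3.3443e-03,1.6399e-01,5.6183e-03
1.0153e+02,1.6979e-01,2.5380e-02,2.7867e-03,1.6196e-01,5.0504e-03
1.0735e+02,1.6674e-01,2.5522e-02,2.3218e-03,1.5988e-01,4.5382e-03
1.1351e+02,1.6377e-01,2.5734e-02,1.9344e-03,1.5776e-01,4.0763e-03
1.2001e+02,1.6087e-01,2.6000e-02,1.6114e-03,1.5560e-01,3.6601e-03
1.2690e+02,1.5803e-01,2.6309e-02,1.3423e-03,1.5340e-01,3.2854e-03
1.3417e+02,1.5523e-01,2.6650e-02,1.1180e-03,1.5117e-01,2.9481e-03
1.4187e+02,1.5248e-01,2.7014e-02,9.3107e-04,1.4890e-01,2.6446e-03
1.5000e+02,1.4976e-01,2.7394e-02,7.7534e-04,1.4661e-01,2.3718e-03
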