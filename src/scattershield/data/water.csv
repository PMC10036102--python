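energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,4.0828e+01,4.0130e+01,4.0128e+01,1.3914e-01,5.6028e-01
5.2867e+00,3.4571e+01,3.3903e+01,3.3902e+01,1.4405e-01,5.2516e-01
5.5899e+00,2.9266e+01,2.8628e+01,2.8626e+01,1.4873e-01,4.9139e-01
5.9104e+00,2.4772e+01,2.4161e+01,2.4159e+01,1.5316e-01,4.5908e-01
6.2493e+00,2.0965e+01,2.0381e+01,2.0379e+01,1.5734e-01,4.2832e-01
6.6076e+00,1.7742e+01,1.7183e+01,1.7181e+01,1.6125e-01,3.9916e-01
6.9865e+00,1.5014e+01,1.4480e+01,1.4478e+01,1.6490e-01,3.7162e-01
7.1106e+00,1.4243e+01,1.3716e+01,1.3714e+01,1.6597e-01,3.6323e-01
7.1134e+00,1.4226e+01,1.3699e+01,1.3697e+01,1.6599e-01,3.6304e-01
7.3871e+00,1.2707e+01,1.2196e+01,1.2193e+01,1.6830e-01,3.4569e-01
7.8107e+00,1.0757e+01,1.0267e+01,1.0264e+01,1.7144e-01,3.2136e-01
8.2586e+00,9.1084e+00,8.6382e+00,8.6355e+00,1.7433e-01,2.9858e-01
8.7321e+00,7.7159e+00,7.2646e+00,7.2616e+00,1.7699e-01,2.7729e-01
8.9772e+00,7.1066e+00,6.6642e+00,6.6612e+00,1.7819e-01,2.6725e-01
8.9808e+00,7.0982e+00,6.6559e+00,6.6529e+00,1.7820e-01,2.6711e-01
9.2329e+00,6.5396e+00,6.1058e+00,6.1027e+00,1.7941e-01,2.5744e-01
9.7623e+00,5.5471e+00,5.1298e+00,5.1265e+00,1.8162e-01,2.3895e-01
1.0322e+01,4.7074e+00,4.3056e+00,4.3020e+00,1.8361e-01,2.2175e-01
1.0914e+01,3.9986e+00,3.6112e+00,3.6074e+00,1.8541e-01,2.0576e-01
1.1540e+01,3.4021e+00,3.0282e+00,3.0242e+00,1.8702e-01,1.9090e-01
1.2201e+01,2.9002e+00,2.5389e+00,2.5346e+00,1.8846e-01,1.7708e-01
1.2901e+01,2.4777e+00,2.1283e+00,2.1238e+00,1.8972e-01,1.6423e-01
1.3033e+01,2.4084e+00,2.0611e+00,2.0565e+00,1.8993e-01,1.6198e-01
1.3038e+01,2.4057e+00,2.0585e+00,2.0539e+00,1.8993e-01,1.6189e-01
1.3641e+01,2.1222e+00,1.7839e+00,1.7791e+00,1.9084e-01,1.5226e-01
1.4423e+01,1.8229e+00,1.4951e+00,1.4900e+00,1.9180e-01,1.4110e-01
1.5197e+01,1.5854e+00,1.2669e+00,1.2615e+00,1.9258e-01,1.3131e-01
1.5203e+01,1.5837e+00,1.2653e+00,1.2599e+00,1.9259e-01,1.3123e-01
1.5250e+01,1.5709e+00,1.2530e+00,1.2476e+00,1.9263e-01,1.3068e-01
1.5858e+01,1.4183e+00,1.1071e+00,1.1014e+00,1.9312e-01,1.2378e-01
1.5864e+01,1.4169e+00,1.1057e+00,1.1000e+00,1.9312e-01,1.2371e-01
1.6125e+01,1.3586e+00,1.0500e+00,1.0443e+00,1.9333e-01,1.2094e-01
1.7049e+01,1.1797e+00,8.8002e-01,8.7399e-01,1.9390e-01,1.1183e-01
1.8027e+01,1.0289e+00,7.3762e-01,7.3125e-01,1.9436e-01,1.0330e-01
1.9060e+01,9.0168e-01,6.1839e-01,6.1167e-01,1.9470e-01,9.5306e-02
2.0153e+01,7.9427e-01,5.1860e-01,5.1152e-01,1.9493e-01,8.7820e-02
2.1309e+01,7.0353e-01,4.3512e-01,4.2766e-01,1.9506e-01,8.0812e-02
2.2531e+01,6.2680e-01,3.6531e-01,3.5747e-01,1.9508e-01,7.4257e-02
2.3823e+01,5.6185e-01,3.0697e-01,2.9872e-01,1.9500e-01,6.8136e-02
2.5189e+01,5.0681e-01,2.5823e-01,2.4956e-01,1.9482e-01,6.2430e-02
2.6633e+01,4.6010e-01,2.1755e-01,2.0844e-01,1.9454e-01,5.7115e-02
2.8160e+01,4.2010e-01,1.8331e-01,1.7376e-01,1.9417e-01,5.2176e-02
2.9775e+01,3.8613e-01,1.5484e-01,1.4482e-01,1.9371e-01,4.7600e-02
3.1482e+01,3.5722e-01,1.3119e-01,1.2070e-01,1.9315e-01,4.3373e-02
3.3288e+01,3.3257e-01,1.1157e-01,1.0059e-01,1.9250e-01,3.9477e-02
3.5196e+01,3.1148e-01,9.5309e-02,8.3825e-02,1.9176e-01,3.5895e-02
3.7215e+01,2.9340e-01,8.1853e-02,6.9852e-02,1.9094e-01,3.2608e-02
3.9349e+01,2.7783e-01,7.0736e-02,5.8204e-02,1.9003e-01,2.9597e-02
4.1605e+01,2.6438e-01,6.1572e-02,4.8497e-02,1.8904e-01,2.6844e-02
4.3991e+01,2.5270e-01,5.4036e-02,4.0406e-02,1.8796e-01,2.4329e-02
4.6513e+01,2.4251e-01,4.7860e-02,3.3663e-02,1.8681e-01,2.2036e-02
4.9180e+01,2.3357e-01,4.2818e-02,2.8044e-02,1.8558e-01,1.9946e-02
5.2000e+01,2.2568e-01,3.8723e-02,2.3362e-02,1.8427e-01,1.8043e-02
5.4982e+01,2.1867e-01,3.5418e-02,1.9461e-02,1.8289e-01,1.6312e-02
5.8135e+01,2.1239e-01,3.2772e-02,1.6210e-02,1.8144e-01,1.4739e-02
6.1468e+01,2.0674e-01,3.0676e-02,1.3501e-02,1.7992e-01,1.3310e-02
6.4993e+01,2.0159e-01,2.9038e-02,1.1245e-02,1.7834e-01,1.2013e-02
6.8719e+01,1.9688e-01,2.7781e-02,9.3647e-03,1.7668e-01,1.0836e-02
7.2660e+01,1.9254e-01,2.6842e-02,7.7987e-03,1.7497e-01,9.7692e-03
7.6826e+01,1.8849e-01,2.6167e-02,6.4942e-03,1.7319e-01,8.8028e-03
8.1232e+01,1.8469e-01,2.5710e-02,5.4076e-03,1.7135e-01,7.9280e-03
8.5890e+01,1.8110e-01,2.5435e-02,4.5026e-03,1.6946e-01,7.1365e-03
8.7987e+01,1.7959e-01,2.5380e-02,4.1595e-03,1.6861e-01,6.8176e-03
8.8022e+01,1.7957e-01,2.5379e-02,4.1540e-03,1.6860e-01,6.8125e-03
9.0815e+01,1.7768e-01,2.5309e-02,3.7489e-03,1.6751e-01,6.4210e-03
9.6022e+01,1.7441e-01,2.5305e-02,3.1211e-03,1.6551e-01,5.7746e-03
1.0153e+02,1.7125e-01,2.5402e-02,2.5984e-03,1.6346e-01,5.1910e-03
1.0735e+02,1.6819e-01,2.5579e-02,2.1630e-03,1.6136e-01,4.6645e-03
1.1351e+02,1.6521e-01,2.5821e-02,1.8006e-03,1.5922e-01,4.1898e-03
1.2001e+02,1.6230e-01,2.6114e-02,1.4987e-03,1.5704e-01,3.7620e-03
1.2690e+02,1.5945e-01,2.6446e-02,1.2474e-03,1.5482e-01,3.3767e-03
1.3417e+02,1.5664e-01,2.6807e-02,1.0382e-03,1.5257e-01,3.0300e-03
1.4187e+02,1.5387e-01,2.7189e-02,8.6405e-04,1.5028e-01,2.7181e-03
1.5000e+02,1.5113e-01,2.7585e-02,7.1906e-04,1.4797e-01,2.4376e-03
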