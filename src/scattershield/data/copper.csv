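energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,1.8476e+02,1.8176e+02,1.8176e+02,8.0365e-02,2.9139e+00
5.2867e+00,1.5874e+02,1.5587e+02,1.5586e+02,8.4511e-02,2.7876e+00
5.5899e+00,1.3636e+02,1.3362e+02,1.3361e+02,8.8665e-02,2.6606e+00
5.9104e+00,1.1713e+02,1.1451e+02,1.1451e+02,9.2803e-02,2.5335e+00
6.2493e+00,1.0060e+02,9.8100e+01,9.8099e+01,9.6901e-02,2.4072e+00
6.6076e+00,8.6401e+01,8.4019e+01,8.4017e+01,1.0094e-01,2.2822e+00
6.9865e+00,7.4199e+01,7.1936e+01,7.1935e+01,1.0489e-01,2.1592e+00
7.1106e+00,7.0714e+01,6.8489e+01,6.8487e+01,1.0609e-01,2.1204e+00
7.1134e+00,7.0637e+01,6.8412e+01,6.8411e+01,1.0611e-01,2.1195e+00
7.3871e+00,6.3718e+01,6.1572e+01,6.1571e+01,1.0873e-01,2.0387e+00
7.8107e+00,5.4717e+01,5.2685e+01,5.2683e+01,1.1245e-01,1.9214e+00
8.2586e+00,4.6987e+01,4.5065e+01,4.5064e+01,1.1603e-01,1.8077e+00
8.7321e+00,4.0351e+01,3.8536e+01,3.8534e+01,1.1946e-01,1.6980e+00
8.9772e+00,3.7406e+01,3.5642e+01,3.5640e+01,1.2110e-01,1.6451e+00
8.9808e+00,2.8942e+02,2.8765e+02,2.8765e+02,1.2112e-01,1.6443e+00
9.2329e+00,2.6672e+02,2.6501e+02,2.6501e+02,1.2272e-01,1.5926e+00
9.7623e+00,2.2971e+02,2.2809e+02,2.2809e+02,1.2580e-01,1.4919e+00
1.0322e+01,1.9898e+02,1.9746e+02,1.9746e+02,1.2870e-01,1.3961e+00
1.0914e+01,1.7220e+02,1.7076e+02,1.7076e+02,1.3141e-01,1.3052e+00
1.1540e+01,1.4887e+02,1.4752e+02,1.4751e+02,1.3392e-01,1.2193e+00
1.2201e+01,1.2847e+02,1.2720e+02,1.2720e+02,1.3625e-01,1.1385e+00
1.2901e+01,1.1076e+02,1.0957e+02,1.0956e+02,1.3840e-01,1.0625e+00
1.3033e+01,1.0780e+02,1.0662e+02,1.0661e+02,1.3875e-01,1.0491e+00
1.3038e+01,1.0769e+02,1.0650e+02,1.0650e+02,1.3876e-01,1.0486e+00
1.3641e+01,9.5433e+01,9.4305e+01,9.4302e+01,1.4036e-01,9.9117e-01
1.4423e+01,8.2167e+01,8.1105e+01,8.1101e+01,1.4215e-01,9.2428e-01
1.5197e+01,7.1366e+01,7.0361e+01,7.0357e+01,1.4367e-01,8.6535e-01
1.5203e+01,7.1289e+01,7.0284e+01,7.0280e+01,1.4368e-01,8.6491e-01
1.5250e+01,7.0698e+01,6.9697e+01,6.9693e+01,1.4377e-01,8.6155e-01
1.5858e+01,6.3599e+01,6.2639e+01,6.2634e+01,1.4480e-01,8.1985e-01
1.5864e+01,6.3530e+01,6.2570e+01,6.2566e+01,1.4481e-01,8.1943e-01
1.6125e+01,6.0789e+01,5.9845e+01,5.9841e+01,1.4524e-01,8.0266e-01
1.7049e+01,5.2234e+01,5.1345e+01,5.1341e+01,1.4656e-01,7.4730e-01
1.8027e+01,4.4853e+01,4.4015e+01,4.4010e+01,1.4774e-01,6.9519e-01
1.9060e+01,3.8472e+01,3.7683e+01,3.7678e+01,1.4879e-01,6.4606e-01
2.0153e+01,3.2985e+01,3.2241e+01,3.2236e+01,1.4972e-01,5.9970e-01
2.1309e+01,2.8269e+01,2.7568e+01,2.7562e+01,1.5052e-01,5.5591e-01
2.2531e+01,2.4217e+01,2.3557e+01,2.3551e+01,1.5121e-01,5.1455e-01
2.3823e+01,2.0738e+01,2.0117e+01,2.0110e+01,1.5179e-01,4.7550e-01
2.5189e+01,1.7752e+01,1.7168e+01,1.7161e+01,1.5226e-01,4.3875e-01
2.6633e+01,1.5193e+01,1.4642e+01,1.4635e+01,1.5257e-01,4.0541e-01
2.8160e+01,1.2995e+01,1.2475e+01,1.2467e+01,1.5275e-01,3.7531e-01
2.9775e+01,1.1115e+01,1.0622e+01,1.0615e+01,1.5281e-01,3.4793e-01
3.1482e+01,9.5084e+00,9.0411e+00,9.0328e+00,1.5275e-01,3.2287e-01
3.3288e+01,8.1353e+00,7.6916e+00,7.6829e+00,1.5258e-01,2.9983e-01
3.5196e+01,6.9623e+00,6.5405e+00,6.5314e+00,1.5232e-01,2.7858e-01
3.7215e+01,5.9606e+00,5.5592e+00,5.5497e+00,1.5196e-01,2.5893e-01
3.9349e+01,5.1039e+00,4.7217e+00,4.7117e+00,1.5151e-01,2.4072e-01
4.1605e+01,4.3688e+00,4.0044e+00,3.9940e+00,1.5098e-01,2.2381e-01
4.3991e+01,3.7431e+00,3.3955e+00,3.3846e+00,1.5036e-01,2.0808e-01
4.6513e+01,3.2105e+00,2.8788e+00,2.8674e+00,1.4967e-01,1.9342e-01
4.9180e+01,2.7572e+00,2.4404e+00,2.4285e+00,1.4890e-01,1.7974e-01
5.2000e+01,2.3713e+00,2.0686e+00,2.0562e+00,1.4806e-01,1.6695e-01
5.4982e+01,2.0426e+00,1.7533e+00,1.7405e+00,1.4714e-01,1.5498e-01
5.8135e+01,1.7627e+00,1.4861e+00,1.4728e+00,1.4616e-01,1.4376e-01
6.1468e+01,1.5242e+00,1.2598e+00,1.2459e+00,1.4511e-01,1.3323e-01
6.4993e+01,1.3210e+00,1.0680e+00,1.0536e+00,1.4400e-01,1.2335e-01
6.8719e+01,1.1477e+00,9.0567e-01,8.9078e-01,1.4282e-01,1.1406e-01
7.2660e+01,9.9979e-01,7.6828e-01,7.5287e-01,1.4158e-01,1.0534e-01
7.6826e+01,8.7355e-01,6.5205e-01,6.3611e-01,1.4028e-01,9.7158e-02
8.1232e+01,7.6570e-01,5.5376e-01,5.3730e-01,1.3892e-01,8.9479e-02
8.5890e+01,6.7349e-01,4.7068e-01,4.5370e-01,1.3751e-01,8.2286e-02
8.7987e+01,6.3781e-01,4.3892e-01,4.2162e-01,1.3688e-01,7.9305e-02
8.8022e+01,6.3723e-01,4.3841e-01,4.2111e-01,1.3687e-01,7.9256e-02
9.0815e+01,5.9459e-01,4.0049e-01,3.8298e-01,1.3605e-01,7.5559e-02
9.6022e+01,5.2701e-01,3.4122e-01,3.2319e-01,1.3453e-01,6.9281e-02
1.0153e+02,4.6905e-01,2.9120e-01,2.7265e-01,1.3297e-01,6.3434e-02
1.0735e+02,4.1930e-01,2.4900e-01,2.2994e-01,1.3136e-01,5.8001e-02
1.1351e+02,3.7653e-01,2.1343e-01,1.9386e-01,1.2971e-01,5.2965e-02
1.2001e+02,3.3971e-01,1.8346e-01,1.6339e-01,1.2801e-01,4.8308e-02
1.2690e+02,3.0796e-01,1.5822e-01,1.3767e-01,1.2628e-01,4.4011e-02
1.3417e+02,2.8053e-01,1.3699e-01,1.1596e-01,1.2451e-01,4.0055e-02
1.4187e+02,2.5677e-01,1.1914e-01,9.7644e-02,1.2271e-01,3.6420e-02
1.5000e+02,2.3616e-01,1.0414e-01,8.2195e-02,1.2088e-01,3.3086e-02
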