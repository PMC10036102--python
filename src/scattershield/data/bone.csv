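energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,1.9021e+02,1.8921e+02,1.8921e+02,1.2570e-01,8.6979e-01
5.2867e+00,1.6377e+02,1.6282e+02,1.6281e+02,1.2985e-01,8.2448e-01
5.5899e+00,1.4089e+02,1.3998e+02,1.3998e+02,1.3383e-01,7.8056e-01
5.9104e+00,1.2112e+02,1.2025e+02,1.2025e+02,1.3761e-01,7.3817e-01
6.2493e+00,1.0406e+02,1.0322e+02,1.0322e+02,1.4121e-01,6.9739e-01
6.6076e+00,8.9338e+01,8.8537e+01,8.8535e+01,1.4461e-01,6.5828e-01
6.9865e+00,7.6646e+01,7.5880e+01,7.5878e+01,1.4781e-01,6.2088e-01
7.1106e+00,7.3011e+01,7.2255e+01,7.2253e+01,1.4875e-01,6.0937e-01
7.1134e+00,7.2930e+01,7.2174e+01,7.2172e+01,1.4877e-01,6.0911e-01
7.3871e+00,6.5715e+01,6.4981e+01,6.4979e+01,1.5082e-01,5.8517e-01
7.8107e+00,5.6305e+01,5.5603e+01,5.5601e+01,1.5363e-01,5.5114e-01
8.2586e+00,4.8211e+01,4.7539e+01,4.7536e+01,1.5626e-01,5.1873e-01
8.7321e+00,4.1257e+01,4.0613e+01,4.0610e+01,1.5870e-01,4.8787e-01
8.9772e+00,3.8167e+01,3.7537e+01,3.7535e+01,1.5983e-01,4.7305e-01
8.9808e+00,3.8125e+01,3.7495e+01,3.7492e+01,1.5984e-01,4.7284e-01
9.2329e+00,3.5272e+01,3.4655e+01,3.4652e+01,1.6098e-01,4.5848e-01
9.7623e+00,3.0134e+01,2.9543e+01,2.9540e+01,1.6309e-01,4.3049e-01
1.0322e+01,2.5736e+01,2.5171e+01,2.5168e+01,1.6504e-01,4.0382e-01
1.0914e+01,2.1976e+01,2.1434e+01,2.1431e+01,1.6684e-01,3.7839e-01
1.1540e+01,1.8762e+01,1.8243e+01,1.8240e+01,1.6849e-01,3.5414e-01
1.2201e+01,1.6017e+01,1.5520e+01,1.5516e+01,1.7001e-01,3.3101e-01
1.2901e+01,1.3672e+01,1.3196e+01,1.3192e+01,1.7139e-01,3.0895e-01
1.3033e+01,1.3284e+01,1.2811e+01,1.2807e+01,1.7162e-01,3.0501e-01
1.3038e+01,1.3269e+01,1.2796e+01,1.2792e+01,1.7163e-01,3.0486e-01
1.3641e+01,1.1671e+01,1.1215e+01,1.1211e+01,1.7264e-01,2.8792e-01
1.4423e+01,9.9635e+00,9.5264e+00,9.5218e+00,1.7377e-01,2.6791e-01
1.5197e+01,8.5913e+00,8.1714e+00,8.1665e+00,1.7472e-01,2.5003e-01
1.5203e+01,8.5816e+00,8.1618e+00,8.1569e+00,1.7472e-01,2.4990e-01
1.5250e+01,8.5069e+00,8.0882e+00,8.0833e+00,1.7478e-01,2.4888e-01
1.5858e+01,7.6157e+00,7.2094e+00,7.2042e+00,1.7540e-01,2.3608e-01
1.5864e+01,7.6071e+00,7.2009e+00,7.1958e+00,1.7541e-01,2.3595e-01
1.6125e+01,7.2650e+00,6.8637e+00,6.8585e+00,1.7567e-01,2.3082e-01
1.7049e+01,6.2064e+00,5.8217e+00,5.8162e+00,1.7644e-01,2.1371e-01
1.8027e+01,5.3032e+00,4.9344e+00,4.9286e+00,1.7710e-01,1.9755e-01
1.9060e+01,4.5337e+00,4.1798e+00,4.1737e+00,1.7764e-01,1.8232e-01
2.0153e+01,3.8791e+00,3.5395e+00,3.5330e+00,1.7807e-01,1.6801e-01
2.1309e+01,3.3225e+00,2.9963e+00,2.9895e+00,1.7839e-01,1.5462e-01
2.2531e+01,2.8492e+00,2.5357e+00,2.5285e+00,1.7860e-01,1.4211e-01
2.3823e+01,2.4469e+00,2.1452e+00,2.1377e+00,1.7871e-01,1.3047e-01
2.5189e+01,2.1049e+00,1.8145e+00,1.8065e+00,1.7871e-01,1.1968e-01
2.6633e+01,1.8144e+00,1.5344e+00,1.5261e+00,1.7860e-01,1.0977e-01
2.8160e+01,1.5653e+00,1.2950e+00,1.2862e+00,1.7839e-01,1.0067e-01
2.9775e+01,1.3542e+00,1.0930e+00,1.0838e+00,1.7808e-01,9.2293e-02
3.1482e+01,1.1753e+00,9.2265e-01,9.1300e-01,1.7768e-01,8.4570e-02
3.3288e+01,1.0236e+00,7.7907e-01,7.6896e-01,1.7718e-01,7.7444e-02
3.5196e+01,8.9497e-01,6.5808e-01,6.4750e-01,1.7660e-01,7.0868e-02
3.7215e+01,7.8584e-01,5.5617e-01,5.4511e-01,1.7593e-01,6.4800e-02
3.9349e+01,6.9318e-01,4.7036e-01,4.5881e-01,1.7517e-01,5.9205e-02
4.1605e+01,6.1446e-01,3.9814e-01,3.8608e-01,1.7433e-01,5.4047e-02
4.3991e+01,5.4752e-01,3.3739e-01,3.2481e-01,1.7341e-01,4.9298e-02
4.6513e+01,4.9055e-01,2.8631e-01,2.7320e-01,1.7242e-01,4.4927e-02
4.9180e+01,4.4200e-01,2.4339e-01,2.2974e-01,1.7134e-01,4.0907e-02
5.2000e+01,4.0057e-01,2.0734e-01,1.9315e-01,1.7020e-01,3.7215e-02
5.4982e+01,3.6516e-01,1.7710e-01,1.6235e-01,1.6898e-01,3.3827e-02
5.8135e+01,3.3484e-01,1.5174e-01,1.3644e-01,1.6769e-01,3.0720e-02
6.1468e+01,3.0883e-01,1.3050e-01,1.1463e-01,1.6633e-01,2.7875e-02
6.4993e+01,2.8646e-01,1.1274e-01,9.6283e-02,1.6490e-01,2.5272e-02
6.8719e+01,2.6716e-01,9.7889e-02,8.0856e-02,1.6341e-01,2.2894e-02
7.2660e+01,2.5047e-01,8.5502e-02,6.7885e-02,1.6186e-01,2.0724e-02
7.6826e+01,2.3598e-01,7.5184e-02,5.6982e-02,1.6025e-01,1.8746e-02
8.1232e+01,2.2334e-01,6.6608e-02,4.7819e-02,1.5858e-01,1.6946e-02
8.5890e+01,2.1228e-01,5.9495e-02,4.0120e-02,1.5685e-01,1.5308e-02
8.7987e+01,2.0791e-01,5.6845e-02,3.7181e-02,1.5608e-01,1.4645e-02
8.8022e+01,2.0784e-01,5.6802e-02,3.7134e-02,1.5607e-01,1.4635e-02
9.0815e+01,2.0255e-01,5.3612e-02,3.3652e-02,1.5507e-01,1.3820e-02
9.6022e+01,1.9394e-01,4.8761e-02,2.8221e-02,1.5324e-01,1.2470e-02
1.0153e+02,1.8627e-01,4.4777e-02,2.3661e-02,1.5137e-01,1.1246e-02
1.0735e+02,1.7941e-01,4.1519e-02,1.9833e-02,1.4944e-01,1.0138e-02
1.1351e+02,1.7323e-01,3.8869e-02,1.6620e-02,1.4748e-01,9.1340e-03
1.2001e+02,1.6762e-01,3.6726e-02,1.3925e-02,1.4547e-01,8.2263e-03
1.2690e+02,1.6250e-01,3.5008e-02,1.1664e-02,1.4343e-01,7.4058e-03
1.3417e+02,1.5779e-01,3.3642e-02,9.7675e-03,1.4136e-01,6.6645e-03
1.4187e+02,1.5342e-01,3.2570e-02,8.1776e-03,1.3925e-01,5.9952e-03
1.5000e+02,1.4935e-01,3.1740e-02,6.8449e-03,1.3712e-01,5.3913e-03
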