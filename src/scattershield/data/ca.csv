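energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,6.0245e+02,6.0062e+02,6.0062e+02,1.1131e-01,1.7203e+00
5.2867e+00,5.2087e+02,5.1911e+02,5.1911e+02,1.1510e-01,1.6398e+00
5.5899e+00,4.4986e+02,4.4818e+02,4.4818e+02,1.1879e-01,1.5612e+00
5.9104e+00,3.8820e+02,3.8659e+02,3.8659e+02,1.2236e-01,1.4846e+00
6.2493e+00,3.3469e+02,3.3316e+02,3.3316e+02,1.2580e-01,1.4106e+00
6.6076e+00,2.8831e+02,2.8685e+02,2.8685e+02,1.2908e-01,1.3393e+00
6.9865e+00,2.4814e+02,2.4674e+02,2.4674e+02,1.3221e-01,1.2709e+00
7.3871e+00,2.1339e+02,2.1205e+02,2.1205e+02,1.3518e-01,1.2053e+00
7.8107e+00,1.8335e+02,1.8207e+02,1.8207e+02,1.3799e-01,1.1427e+00
8.2586e+00,1.5739e+02,1.5617e+02,1.5617e+02,1.4065e-01,1.0828e+00
8.7321e+00,1.3501e+02,1.3384e+02,1.3384e+02,1.4316e-01,1.0255e+00
9.2329e+00,1.1566e+02,1.1455e+02,1.1455e+02,1.4553e-01,9.7067e-01
9.7623e+00,9.9007e+01,9.7944e+01,9.7942e+01,1.4777e-01,9.1794e-01
1.0322e+01,8.4711e+01,8.3697e+01,8.3694e+01,1.4990e-01,8.6716e-01
1.0914e+01,7.2447e+01,7.1480e+01,7.1477e+01,1.5192e-01,8.1812e-01
1.1540e+01,6.1932e+01,6.1011e+01,6.1007e+01,1.5383e-01,7.7067e-01
1.2201e+01,5.2920e+01,5.2043e+01,5.2040e+01,1.5565e-01,7.2469e-01
1.2901e+01,4.5202e+01,4.4368e+01,4.4364e+01,1.5737e-01,6.8013e-01
1.3641e+01,3.8594e+01,3.7802e+01,3.7798e+01,1.5899e-01,6.3696e-01
1.4423e+01,3.2940e+01,3.2188e+01,3.2184e+01,1.6051e-01,5.9520e-01
1.5250e+01,2.8104e+01,2.7392e+01,2.7388e+01,1.6192e-01,5.5491e-01
1.6125e+01,2.3971e+01,2.3297e+01,2.3292e+01,1.6323e-01,5.1614e-01
1.7049e+01,2.0440e+01,1.9802e+01,1.9797e+01,1.6443e-01,4.7900e-01
1.8027e+01,1.7419e+01,1.6816e+01,1.6810e+01,1.6551e-01,4.4356e-01
1.9060e+01,1.4840e+01,1.4270e+01,1.4264e+01,1.6648e-01,4.0991e-01
2.0153e+01,1.2643e+01,1.2104e+01,1.2098e+01,1.6731e-01,3.7811e-01
2.1309e+01,1.0772e+01,1.0262e+01,1.0256e+01,1.6802e-01,3.4823e-01
2.2531e+01,9.1796e+00,8.6975e+00,8.6907e+00,1.6860e-01,3.2027e-01
2.3823e+01,7.8242e+00,7.3681e+00,7.3610e+00,1.6905e-01,2.9423e-01
2.5189e+01,6.6713e+00,6.2394e+00,6.2319e+00,1.6938e-01,2.7011e-01
2.6633e+01,5.6913e+00,5.2815e+00,5.2736e+00,1.6956e-01,2.4819e-01
2.8160e+01,4.8496e+00,4.4600e+00,4.4517e+00,1.6961e-01,2.2826e-01
2.9775e+01,4.1362e+00,3.7654e+00,3.7566e+00,1.6954e-01,2.1001e-01
3.1482e+01,3.5319e+00,3.1786e+00,3.1694e+00,1.6936e-01,1.9321e-01
3.3288e+01,3.0201e+00,2.6829e+00,2.6733e+00,1.6908e-01,1.7769e-01
3.5196e+01,2.5864e+00,2.2644e+00,2.2543e+00,1.6870e-01,1.6334e-01
3.7215e+01,2.2188e+00,1.9111e+00,1.9006e+00,1.6822e-01,1.5004e-01
3.9349e+01,1.9073e+00,1.6130e+00,1.6020e+00,1.6765e-01,1.3773e-01
4.1605e+01,1.6432e+00,1.3615e+00,1.3499e+00,1.6700e-01,1.2631e-01
4.3991e+01,1.4193e+00,1.1493e+00,1.1373e+00,1.6625e-01,1.1573e-01
4.6513e+01,1.2293e+00,9.7047e-01,9.5790e-01,1.6543e-01,1.0594e-01
4.9180e+01,1.0680e+00,8.1972e-01,8.0662e-01,1.6452e-01,9.6872e-02
5.2000e+01,9.3109e-01,6.9270e-01,6.7907e-01,1.6353e-01,8.8491e-02
5.4982e+01,8.1476e-01,5.8573e-01,5.7155e-01,1.6246e-01,8.0749e-02
5.8135e+01,7.1586e-01,4.9566e-01,4.8094e-01,1.6132e-01,7.3606e-02
6.1468e+01,6.3172e-01,4.1988e-01,4.0459e-01,1.6010e-01,6.7024e-02
6.4993e+01,5.6007e-01,3.5613e-01,3.4029e-01,1.5882e-01,6.0968e-02
6.8719e+01,4.9899e-01,3.0254e-01,2.8613e-01,1.5746e-01,5.5404e-02
7.2660e+01,4.4687e-01,2.5752e-01,2.4053e-01,1.5604e-01,5.0300e-02
7.6826e+01,4.0233e-01,2.1971e-01,2.0215e-01,1.5455e-01,4.5624e-02
8.1232e+01,3.6420e-01,1.8798e-01,1.6986e-01,1.5300e-01,4.1349e-02
8.5890e+01,3.3152e-01,1.6138e-01,1.4268e-01,1.5139e-01,3.7445e-02
9.0815e+01,3.0344e-01,1.3910e-01,1.1983e-01,1.4973e-01,3.3885e-02
9.6022e+01,2.7926e-01,1.2045e-01,1.0061e-01,1.4801e-01,3.0644e-02
1.0153e+02,2.5838e-01,1.0485e-01,8.4452e-02,1.4624e-01,2.7696e-02
1.0735e+02,2.4031e-01,9.1828e-02,7.0872e-02,1.4442e-01,2.5017e-02
1.1351e+02,2.2460e-01,8.0966e-02,5.9461e-02,1.4255e-01,2.2585e-02
1.2001e+02,2.1090e-01,7.1920e-02,4.9875e-02,1.4065e-01,2.0380e-02
1.2690e+02,1.9891e-01,6.4398e-02,4.1824e-02,1.3870e-01,1.8382e-02
1.3417e+02,1.8836e-01,5.8156e-02,3.5064e-02,1.3672e-01,1.6572e-02
1.4187e+02,1.7903e-01,5.2986e-02,2.9389e-02,1.3471e-01,1.4934e-02
1.5000e+02,1.7074e-01,4.8713e-02,2.4626e-02,1.3267e-01,1.3452e-02
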