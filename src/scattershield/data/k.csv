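energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh
5.0000e+00,5.1949e+02,5.1778e+02,5.1778e+02,1.0801e-01,1.5983e+00
5.2867e+00,4.4835e+02,4.4672e+02,4.4672e+02,1.1177e-01,1.5227e+00
5.5899e+00,3.8661e+02,3.8505e+02,3.8505e+02,1.1540e-01,1.4494e+00
5.9104e+00,3.3308e+02,3.3159e+02,3.3159e+02,1.1887e-01,1.3786e+00
6.2493e+00,2.8672e+02,2.8529e+02,2.8529e+02,1.2220e-01,1.3106e+00
6.6076e+00,2.4660e+02,2.4523e+02,2.4523e+02,1.2537e-01,1.2453e+00
6.9865e+00,2.1192e+02,2.1061e+02,2.1060e+02,1.2837e-01,1.1828e+00
7.3871e+00,1.8193e+02,1.8068e+02,1.8068e+02,1.3123e-01,1.1230e+00
7.8107e+00,1.5605e+02,1.5485e+02,1.5485e+02,1.3393e-01,1.0657e+00
8.2586e+00,1.3377e+02,1.3262e+02,1.3262e+02,1.3650e-01,1.0107e+00
8.7321e+00,1.1460e+02,1.1350e+02,1.1350e+02,1.3895e-01,9.5776e-01
9.2329e+00,9.8058e+01,9.7013e+01,9.7010e+01,1.4127e-01,9.0670e-01
9.7623e+00,8.3843e+01,8.2845e+01,8.2843e+01,1.4349e-01,8.5730e-01
1.0322e+01,7.1658e+01,7.0706e+01,7.0703e+01,1.4561e-01,8.0940e-01
1.0914e+01,6.1218e+01,6.0311e+01,6.0308e+01,1.4763e-01,7.6287e-01
1.1540e+01,5.2278e+01,5.1414e+01,5.1411e+01,1.4956e-01,7.1765e-01
1.2201e+01,4.4626e+01,4.3805e+01,4.3801e+01,1.5140e-01,6.7369e-01
1.2901e+01,3.8080e+01,3.7299e+01,3.7296e+01,1.5314e-01,6.3102e-01
1.3641e+01,3.2482e+01,3.1742e+01,3.1738e+01,1.5479e-01,5.8969e-01
1.4423e+01,2.7699e+01,2.6997e+01,2.6992e+01,1.5633e-01,5.4977e-01
1.5250e+01,2.3612e+01,2.2947e+01,2.2943e+01,1.5777e-01,5.1135e-01
1.6125e+01,2.0115e+01,1.9487e+01,1.9482e+01,1.5909e-01,4.7453e-01
1.7049e+01,1.7130e+01,1.6535e+01,1.6530e+01,1.6029e-01,4.3941e-01
1.8027e+01,1.4587e+01,1.4024e+01,1.4019e+01,1.6137e-01,4.0609e-01
1.9060e+01,1.2421e+01,1.1890e+01,1.1884e+01,1.6232e-01,3.7463e-01
2.0153e+01,1.0579e+01,1.0076e+01,1.0070e+01,1.6315e-01,3.4509e-01
2.1309e+01,9.0106e+00,8.5356e+00,8.5293e+00,1.6384e-01,3.1747e-01
2.2531e+01,7.6770e+00,7.2275e+00,7.2209e+00,1.6439e-01,2.9177e-01
2.3823e+01,6.5432e+00,6.1174e+00,6.1104e+00,1.6482e-01,2.6796e-01
2.5189e+01,5.5795e+00,5.1757e+00,5.1684e+00,1.6512e-01,2.4598e-01
2.6633e+01,4.7609e+00,4.3774e+00,4.3696e+00,1.6529e-01,2.2596e-01
2.8160e+01,4.0590e+00,3.6941e+00,3.6860e+00,1.6533e-01,2.0768e-01
2.9775e+01,3.4644e+00,3.1168e+00,3.1082e+00,1.6526e-01,1.9090e-01
3.1482e+01,2.9609e+00,2.6294e+00,2.6204e+00,1.6508e-01,1.7543e-01
3.3288e+01,2.5345e+00,2.2180e+00,2.2086e+00,1.6480e-01,1.6114e-01
3.5196e+01,2.1734e+00,1.8709e+00,1.8611e+00,1.6443e-01,1.4792e-01
3.7215e+01,1.8675e+00,1.5781e+00,1.5678e+00,1.6396e-01,1.3568e-01
3.9349e+01,1.6082e+00,1.3313e+00,1.3205e+00,1.6340e-01,1.2435e-01
4.1605e+01,1.3885e+00,1.1231e+00,1.1119e+00,1.6276e-01,1.1386e-01
4.3991e+01,1.2022e+00,9.4773e-01,9.3598e-01,1.6203e-01,1.0416e-01
4.6513e+01,1.0441e+00,7.9998e-01,7.8773e-01,1.6122e-01,9.5184e-02
4.9180e+01,9.1002e-01,6.7555e-01,6.6279e-01,1.6033e-01,8.6895e-02
5.2000e+01,7.9614e-01,5.7081e-01,5.5753e-01,1.5936e-01,7.9245e-02
5.4982e+01,6.9938e-01,4.8268e-01,4.6886e-01,1.5832e-01,7.2193e-02
5.8135e+01,6.1711e-01,4.0855e-01,3.9420e-01,1.5720e-01,6.5702e-02
6.1468e+01,5.4709e-01,3.4624e-01,3.3135e-01,1.5601e-01,5.9733e-02
6.4993e+01,4.8745e-01,2.9388e-01,2.7844e-01,1.5475e-01,5.4254e-02
6.8719e+01,4.3658e-01,2.4992e-01,2.3392e-01,1.5343e-01,4.9232e-02
7.2660e+01,3.9315e-01,2.1302e-01,1.9648e-01,1.5204e-01,4.4635e-02
7.6826e+01,3.5600e-01,1.8208e-01,1.6498e-01,1.5058e-01,4.0435e-02
8.1232e+01,3.2417e-01,1.5616e-01,1.3850e-01,1.4907e-01,3.6602e-02
8.5890e+01,2.9684e-01,1.3446e-01,1.1624e-01,1.4749e-01,3.3108e-02
9.0815e+01,2.7333e-01,1.1630e-01,9.7528e-02,1.4587e-01,2.9929e-02
9.6022e+01,2.5304e-01,1.0114e-01,8.1810e-02,1.4419e-01,2.7040e-02
1.0153e+02,2.3548e-01,8.8482e-02,6.8608e-02,1.4246e-01,2.4415e-02
1.0735e+02,2.2024e-01,7.7936e-02,5.7521e-02,1.4068e-01,2.2035e-02
1.1351e+02,2.0696e-01,6.9163e-02,4.8214e-02,1.3887e-01,1.9877e-02
1.2001e+02,1.9533e-01,6.1876e-02,4.0402e-02,1.3701e-01,1.7922e-02
1.2690e+02,1.8511e-01,5.5837e-02,3.3847e-02,1.3511e-01,1.6152e-02
1.3417e+02,1.7608e-01,5.0842e-02,2.8348e-02,1.3318e-01,1.4551e-02
1.4187e+02,1.6805e-01,4.6721e-02,2.3737e-02,1.3121e-01,1.3104e-02
1.5000e+02,1.6089e-01,4.3332e-02,1.9870e-02,1.2922e-01,1.1796e-02
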