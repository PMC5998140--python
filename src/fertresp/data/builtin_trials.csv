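site_id,treatment,n_rate,p_rate,k_rate,yield_mean,yield_sd,reps
Pinghe-low,N0P0K0,0,0,0,4320,91,3
Pinghe-low,N0P2K2,0,75,105,5325,153,3
Pinghe-low,N1P2K2,82.5,75,105,6120,494,3
Pinghe-low,N2P0K2,165,0,105,5985,744,3
Pinghe-low,N2P1K2,165,37.5,105,6390,716,3
Pinghe-low,N2P2K2,165,75,105,6581,744,3
Pinghe-low,N2P3K2,165,112.5,105,6559,563,3
Pinghe-low,N2P2K0,165,75,0,5760,551,3
Pinghe-low,N2P2K1,165,75,52.5,6176,671,3
Pinghe-low,N2P2K3,165,75,157.5,6270,814,3
Pinghe-low,N3P2K2,247.5,75,105,6326,611,3
Pinghe-low,N1P1K2,82.5,37.5,105,6165,690,3
Pinghe-low,N1P2K1,82.5,75,52.5,6113,603,3
Pinghe-low,N2P1K1,165,37.5,52.5,6304,732,3
Pinghe-medium,N0P0K0,0,0,0,5180,518,3
Pinghe-medium,N0P2K2,0,75,105,6375,778,3
Pinghe-medium,N1P2K2,82.5,75,105,6995,576,3
Pinghe-medium,N2P0K2,165,0,105,7115,348,3
Pinghe-medium,N2P1K2,165,37.5,105,7155,131,3
Pinghe-medium,N2P2K2,165,75,105,7190,90,3
Pinghe-medium,N2P3K2,165,112.5,105,7330,128,3
Pinghe-medium,N2P2K0,165,75,0,7010,310,3
Pinghe-medium,N2P2K1,165,75,52.5,7120,111,3
Pinghe-medium,N2P2K3,165,75,157.5,7270,230,3
Pinghe-medium,N3P2K2,247.5,75,105,7395,541,3
Pinghe-medium,N1P1K2,82.5,37.5,105,7295,150,3
Pinghe-medium,N1P2K1,82.5,75,52.5,7185,303,3
Pinghe-medium,N2P1K1,165,37.5,52.5,7215,278,3
Pinghe-high,N0P0K0,0,0,0,5835,325,3
Pinghe-high,N0P2K2,0,75,105,6835,458,3
Pinghe-high,N1P2K2,82.5,75,105,7675,621,3
Pinghe-high,N2P0K2,165,0,105,7905,1105,3
Pinghe-high,N2P1K2,165,37.5,105,8090,1089,3
Pinghe-high,N2P2K2,165,75,105,8465,1218,3
Pinghe-high,N2P3K2,165,112.5,105,8480,1330,3
Pinghe-high,N2P2K0,165,75,0,8040,1001,3
Pinghe-high,N2P2K1,165,75,52.5,8180,998,3
Pinghe-high,N2P2K3,165,75,157.5,8525,1201,3
Pinghe-high,N3P2K2,247.5,75,105,8460,1182,3
Pinghe-high,N1P1K2,82.5,37.5,105,8280,1081,3
Pinghe-high,N1P2K1,82.5,75,52.5,8025,754,3
Pinghe-high,N2P1K1,165,37.5,52.5,8125,979,3
Xianyou-low,N0P0K0,0,0,0,4858,162,4
Xianyou-low,N0P2K2,0,56,109,5520,436,4
Xianyou-low,N1P2K2,82.5,56,109,6568,553,4
Xianyou-low,N2P0K2,165,0,109,6654,555,4
Xianyou-low,N2P1K2,165,28,109,7031,665,4
Xianyou-low,N2P2K2,165,56,109,7331,483,4
Xianyou-low,N2P3K2,165,84,109,7078,494,4
Xianyou-low,N2P2K0,165,56,0,6416,601,4
Xianyou-low,N2P2K1,165,56,54.5,6917,424,4
Xianyou-low,N2P2K3,165,56,163.5,7005,443,4
Xianyou-low,N3P2K2,247.5,56,109,6754,640,4
Xianyou-low,N1P1K2,82.5,28,109,6538,550,4
Xianyou-low,N1P2K1,82.5,56,54.5,6675,547,4
Xianyou-low,N2P1K1,165,28,54.5,6763,573,4
Xianyou-medium,N0P0K0,0,0,0,5415,288,4
Xianyou-medium,N0P2K2,0,56,109,5907,382,4
Xianyou-medium,N1P2K2,82.5,56,109,6741,633,4
Xianyou-medium,N2P0K2,165,0,109,6831,608,4
Xianyou-medium,N2P1K2,165,28,109,7302,678,4
Xianyou-medium,N2P2K2,165,56,109,7689,574,4
Xianyou-medium,N2P3K2,165,84,109,7236,760,4
Xianyou-medium,N2P2K0,165,56,0,6495,791,4
Xianyou-medium,N2P2K1,165,56,54.5,7326,665,4
Xianyou-medium,N2P2K3,165,56,163.5,7107,605,4
Xianyou-medium,N3P2K2,247.5,56,109,6774,646,4
Xianyou-medium,N1P1K2,82.5,28,109,6717,766,4
Xianyou-medium,N1P2K1,82.5,56,54.5,6957,925,4
Xianyou-medium,N2P1K1,165,28,54.5,6930,510,4
Xianyou-high,N0P0K0,0,0,0,6375,457,4
Xianyou-high,N0P2K2,0,53,112,7080,838,4
Xianyou-high,N1P2K2,82.5,53,112,7587,562,4
Xianyou-high,N2P0K2,165,0,112,7533,536,4
Xianyou-high,N2P1K2,165,26.5,112,7767,702,4
Xianyou-high,N2P2K2,165,53,112,8025,697,4
Xianyou-high,N2P3K2,165,79.5,112,7926,748,4
Xianyou-high,N2P2K0,165,53,0,7965,483,4
Xianyou-high,N2P2K1,165,53,56,7563,538,4
Xianyou-high,N2P2K3,165,53,168,7770,529,4
Xianyou-high,N3P2K2,247.5,53,112,7794,468,4
Xianyou-high,N1P1K2,82.5,26.5,112,7617,613,4
Xianyou-high,N1P2K1,82.5,53,56,7962,631,4
Xianyou-high,N2P1K1,165,26.5,56,7827,302,4
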