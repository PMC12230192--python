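cluster_id,lat,lon,area_km2,builtup,crop,open,others,water,nearest_powerline_m,road_density_km_per_km2,ndvi_mean
1,17.8132,75.87388,22.94,2.06,22.22,75.40,0.21,0.11,840.34,0.58,0.23
2,18.00682,75.86083,22.94,1.16,48.04,49.55,0.00,1.25,2891.83,0.09,0.21
3,17.45103,76.21547,25.42,0.61,62.95,33.56,0.00,2.87,0.00,0.71,0.25
4,17.93501,76.40594,45.80,1.74,23.95,71.67,0.03,2.61,10318.24,0.40,0.43
5,18.02985,76.29699,22.94,0.03,31.46,65.61,0.60,2.31,2309.19,0.31,0.36
6,18.25485,76.32934,71.81,0.89,44.05,49.77,1.93,3.37,502.66,0.14,0.16
7,17.9312,75.72263,22.94,1.35,37.07,57.32,2.10,2.17,5277.44,0.23,0.42
8,17.98588,75.73365,22.94,0.92,41.19,55.96,0.08,1.85,1872.52,0.25,0.39
9,17.37725,76.02758,42.48,0.05,77.22,22.73,0.00,0.00,3270.37,0.25,0.39
10,17.34404,75.74915,22.94,0.46,44.77,53.33,0.13,1.32,1911.17,0.80,0.30
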