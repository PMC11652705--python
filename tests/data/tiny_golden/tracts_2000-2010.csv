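tract_id,region_id,urban_block_share,median_hh_income_start,housing_built_prior_two_decades_share_start,median_home_value_start,median_home_value_end,bachelors_share_start,bachelors_share_end,median_rent_start,median_rent_end,low_income_hh_count_start,low_income_hh_count_end,low_income_hh_share_start,low_income_hh_share_end
R00-T000,R00,0.720854,49410.14,0.062252,234860.82,527805.66,0.193052,0.289079,1558.35,1830.58,1475,1492,0.651567,0.670998
R00-T001,R00,0.787846,39924.87,0.208041,191801.53,290465.69,0.161427,0.262927,1238,1433.08,1162,1176,0.61535,0.628731
R00-T002,R00,0.725674,35601.27,0.089511,526342.21,792607.17,0.214499,0.214499,1432.45,1650.15,1052,1081,0.622218,0.63995
R00-T003,R00,0.608642,49342.2,0.146117,307286.28,332588.77,0.17228,0.17228,857.4,994.7,560,570,0.511519,0.524978
R00-T004,R00,0.755964,44163.19,0.124642,316039.51,347613.82,0.298884,0.298884,949.21,1096.41,848,788,0.672131,0.681959
R00-T005,R00,0.748747,41524.74,0.298756,451022.69,501227.73,0.178789,0.178789,1098.9,1297.47,739,758,0.58102,0.586491
R00-T006,R00,0.644562,78071,0.370607,268412.37,300640.41,0.467482,0.489499,1143.09,1306.78,557,570,0.252107,0.265877
R00-T007,R00,0.809337,96137.17,0.541047,268412.37,399952.98,0.369521,0.386358,1121.92,1296.65,432,454,0.199847,0.21168
R00-T008,R00,0.745303,109624.64,0.613684,268412.37,527805.66,0.516384,0.528236,1661.83,1904.01,307,330,0.261495,0.211495
R00-T009,R00,0.65195,129881.93,0.50855,469721.64,596578.96,0.457717,0.468476,902.11,1056.58,241,259,0.245839,0.260561
R00-T010,R00,0.097588,70664.94,0.539513,305466.35,379438.74,0.435519,0.461584,1609.09,1865.58,275,295,0.30694,0.313029
R00-T011,R00,0.702789,92108.74,0.60209,432682.54,546730.48,0.426249,0.449911,1070.34,1244.01,345,373,0.201891,0.218697
R01-T000,R01,0.725945,45699.36,0.092758,270424.3,579892.79,0.140412,0.235211,1831.88,2040.28,1237,1259,0.536822,0.539448
R01-T001,R01,0.871856,49170.05,0.266174,230709.09,323926.02,0.199443,0.300103,1805.81,2011.85,879,893,0.669824,0.682458
R01-T002,R01,0.8818,38000.14,0.160329,466549.16,653122.02,0.244072,0.244072,1374.7,1499.8,1397,1421,0.697909,0.713316
R01-T003,R01,0.86718,50260.42,0.253951,269458.21,272752.43,0.231559,0.231559,1474.08,1607.08,957,963,0.642946,0.650546
R01-T004,R01,0.684181,49637.65,0.210578,269006.09,266917.79,0.13325,0.13325,1610.87,1756.73,1077,1017,0.463177,0.482579
R01-T005,R01,0.900034,39627.82,0.14999,614482.93,619911.53,0.172524,0.172524,1815.34,1993.2,901,916,0.611131,0.618139
R01-T006,R01,0.573446,89295.45,0.452656,309056.35,316059.69,0.371009,0.38756,1808.81,1986.1,631,632,0.327054,0.346128
R01-T007,R01,0.586789,112773.88,0.671743,309056.35,430410.53,0.485362,0.504074,1444.87,1601.44,220,239,0.175489,0.179769
R01-T008,R01,0.660006,104944.94,0.392291,309056.35,579892.79,0.500168,0.527469,1280.97,1432.94,497,508,0.208791,0.158791
R01-T009,R01,0.621253,145800.04,0.607377,540848.6,634231.74,0.360476,0.370701,1509.44,1645.83,482,501,0.263177,0.280522
R01-T010,R01,0.13524,77576.45,0.421917,375111.87,439698.71,0.534224,0.549716,1771.05,1943.61,355,356,0.14837,0.15304
R01-T011,R01,0.573505,131559.79,0.518795,373901.62,434762.59,0.463693,0.480598,1193.44,1326.61,570,589,0.32376,0.32795
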