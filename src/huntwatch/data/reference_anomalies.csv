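year,province,region,excess_mortality_pct,observed,pred_median,pred_lo,pred_hi,printed_delta_median,printed_delta_lo,printed_delta_hi
2020,Milan,Lombardy,32,5067,5640,5463,5823,573,396,756
2020,Cremona,Lombardy,52,2879,3386,3278,3498,507,399,619
2020,Lodi,Lombardy,47,1176,1660,1578,1746,484,402,570
2020,Bergamo,Lombardy,60,9061,9530,9236,9835,469,175,774
2020,Pavia,Lombardy,32,3726,4166,4034,4303,440,308,577
2020,Massa Carrara,Tuscany,16,1490,1792,1732,1854,302,242,364
2020,Bologna,Emilia-Romagna,13,4882,5152,4990,5320,270,108,438
2020,Siena,Tuscany,1,6824,7060,6841,7288,236,17,464
2020,Varese,Lombardy,27,2460,2653,2567,2742,193,107,282
2020,Parma,Emilia-Romagna,31,3274,3444,3330,3563,170,56,289
2020,Modena,Emilia-Romagna,16,3496,3659,3543,3780,163,47,284
2020,Reggio Emilia,Emilia-Romagna,15,2924,3045,2947,3146,121,23,222
2020,Ferrara,Emilia-Romagna,8,1811,1895,1832,1960,84,21,149
2020,Monza and Brianza,Lombardy,33,1519,1573,1520,1629,54,2,110
2021,Milan,Lombardy,8,4991,5449,5275,5629,458,284,638
2021,Lodi,Lombardy,5,1147,1604,1524,1688,457,377,541
2021,Cremona,Lombardy,2,2879,3271,3165,3382,392,286,503
2021,Bergamo,Lombardy,2,8817,9207,8918,9508,390,101,691
2021,Pavia,Lombardy,5,3694,4025,3895,4160,331,201,466
2021,Siena,Tuscany,7,6514,6821,6605,7046,307,91,532
2021,Pisa,Tuscany,7,7160,7408,7174,7651,248,14,491
2021,Bologna,Emilia-Romagna,9,4749,4977,4818,5143,228,69,394
2021,Prato,Tuscany,21,2186,2372,2294,2454,186,108,268
2021,Modena,Emilia-Romagna,9,3387,3536,3421,3655,149,34,268
2021,Parma,Emilia-Romagna,5,3205,3328,3215,3445,123,10,240
2021,Reggio Emilia,Emilia-Romagna,7,2838,2942,2846,3042,104,8,204
2021,Varese,Lombardy,13,2467,2563,2479,2651,96,12,184
2021,Monza and Brianza,Lombardy,12,1437,1520,1468,1574,84,31,137
2021,Ferrara,Emilia-Romagna,10,1752,1830,1769,1895,78,17,143
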