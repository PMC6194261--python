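year,avg_birds,avg_birds_sd,max_birds,cow_days,cow_days_sd,pct_util,pct_util_sd,precip,pmdi_avg,pmdi_min,tmax,hot_days
2004,8,9,35,,,,,69.55,0.53,-3.85,38.33,27
2005,11,9,36,2.0,0.8,,,33.7,3.36,-0.06,38.89,22
2006,15,13,67,1.0,0.5,,,47.78,-1.55,-3.92,39.44,41
2007,8,8,44,1.2,0.5,61,24,45.57,0.09,-2.59,40.56,12
2008,9,12,65,0.9,0.6,50,27,31.88,-1.36,-3.31,40.00,30
2009,5,7,28,1.4,0.9,46,18,43.1,-2.22,-3.55,39.44,37
2010,3,3,10,1.0,0.7,52,27,43.36,0.85,-1.09,39.44,36
2011,6,10,51,0.4,0.3,,,20.47,-3.74,-6.18,42.78,84
2012,3,5,14,,,59,23,21.11,-4.56,-5.86,41.11,59
2013,2,4,21,0.2,0.1,,,46.46,-3.25,-5.01,40.00,35
2014,1,2,5,0.2,0.2,,,31.678,-2.62,-3.4,41.11,27
2015,1,2,9,0.3,0.2,,,66.09,2.72,-0.09,40.56,44
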