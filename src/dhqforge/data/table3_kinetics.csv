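code,vmax_umol_l_s,km_umol_l,kcat_per_s,efficiency_l_umol_s,specific_activity_u_mg
3001,2.56,281.43,52.26,0.19,119.14
3002,4.57,187.68,29.53,0.16,57.34
3003,1.34,210.71,13.53,0.06,34.72
3004,,,,,
3005,15.50,870.37,208.96,0.24,93.91
3006,6.39,478.67,102.15,0.21,187.69
3007,2.43,777.75,77.06,0.10,84.95
3008,2.46,624.52,23.96,0.04,46.37
3009,4.24,203.24,31.67,0.16,75.06
3010,0.80,202.55,10.59,0.05,9.39
3011,0.57,158.79,7.15,0.05,15.06
3012,66.67,448.50,185.43,0.41,369.99
3013,7.04,159.89,4.63,0.03,86.50
3014,3.60,151.51,3.83,0.03,91.93
3015,4.18,46.14,10.00,0.22,67.71
3016,12.42,141.53,211.83,1.50,501.87
3017,8.25,1218.56,11.92,0.01,30.19
3018,0.68,400.82,9.06,0.02,15.64
3019,,,,,
3020,0.96,107.07,10.46,0.10,62.27
3021,2.16,133.97,5.33,0.04,15.90
3022,8.26,601.64,119.98,0.20,195.81
3023,2.86,67.88,42.20,0.62,68.99
3024,6.23,526.07,75.11,0.14,131.08
3025,5.89,368.46,59.61,0.16,117.89
3026,2.95,304.54,3.80,0.01,5.16
3027,6.00,255.54,50.20,0.20,116.07
3028,1.16,180.72,6.88,0.04,17.66
3029,,,,,
3030,1.14,92.76,3.86,0.04,8.58
3031,1.45,37.16,5.95,0.16,19.82
3032,12.35,617.28,78.87,0.13,105.18
3033,2.64,150.25,57.84,0.38,155.93
3034,3.78,345.90,37.97,0.11,71.87
3035,11.14,2226.50,192.27,0.09,136.57
3036,9.64,131.63,102.70,0.78,192.10
3037,3.87,119.97,73.18,0.61,365.73
3038,,,,,
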