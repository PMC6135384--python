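sample_id,lat,lon,depth,mean_chl,mean_sst,mean_sss,omega_arag,chl_anom,sst_anom,sss_anom,n_specimens,pH
DAR-B-43,1.673564,-91.992128,13,0.21,25.56,33.54,3.20,0.04,3.32,0.38,318,8.07
BAL-1,-0.488667,-90.270583,4,0.36,23.80,34.11,2.90,0.12,2.77,0.15,315,7.94
BAL-2,-0.488667,-90.270583,4,0.36,23.80,34.11,2.90,0.12,2.77,0.15,316,7.94
SF-7,-0.804000,-90.037900,4,0.35,23.48,34.25,3.18,0.10,2.52,0.22,308,7.97
SF-13,-0.805520,-90.034133,29,0.35,23.48,34.25,3.18,0.10,2.52,0.22,331,7.97
SC-33,-0.849350,-89.560917,26,0.49,23.44,34.24,2.67,0.17,2.73,0.22,310,7.90
SC-35,-0.850633,-89.568833,27,0.49,23.44,34.24,2.67,0.17,2.73,0.22,292,7.90
SC-48,-0.885283,-89.607867,30,0.49,23.44,34.24,2.67,0.17,2.73,0.22,339,7.90
ES-59,-1.344117,-89.649233,14,0.30,23.53,34.40,3.15,0.11,2.58,0.25,337,8.03
ES-63,-1.345133,-89.656050,19,0.30,23.53,34.40,3.15,0.11,2.58,0.25,304,8.03
FL-96,-1.217083,-90.430950,34,0.33,23.41,34.25,2.83,0.07,2.04,0.18,312,7.91
FL-97,-1.215400,-90.428183,28,0.33,23.41,34.25,2.83,0.07,2.04,0.18,316,7.91
FL-102,-1.213900,-90.425933,31,0.33,23.41,34.25,2.83,0.07,2.04,0.18,336,7.91
FL-105,-1.216333,-90.423850,17,0.33,23.41,34.25,2.83,0.07,2.04,0.18,293,7.91
FL-117,-1.228400,-90.415400,31,0.33,23.41,34.25,2.83,0.07,2.04,0.18,312,7.91
IS_EB-121,-0.656333,-91.197683,18,2.01,22.96,34.23,2.45,0.52,2.17,0.24,329,7.88
IS_EB-145,-0.590583,-91.095050,46,2.01,22.96,34.23,2.45,0.52,2.17,0.24,352,7.88
IS_EB-148,-0.577883,-91.103900,42,2.01,22.96,34.23,2.45,0.52,2.17,0.24,475,7.88
IS_UB-149,-0.401533,-91.226917,42,2.01,22.96,34.23,2.45,0.52,2.17,0.24,317,7.88
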