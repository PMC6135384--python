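sample_id,Ah,Bsp,Cf,Cl,Csp,Cs,Ecs,Em,Ep,Gv,Mb,Msp,NHsp,Nsp,Pd,Pc,Qb,Qg,Qs,Rmc,Rmg,Sm,Sg,Ta,Usp1,Usp2,Usp3,Usp4
DAR-B-43,18.24,4.4,0.63,0.0,3.77,4.72,0.0,0.0,0.0,0.0,0.0,0.0,0.0,2.83,0.0,1.57,0.31,0.0,0.94,5.35,0.0,14.15,0.31,0.0,0.0,0.0,0.0,0.0
BAL-1,13.02,1.59,0.0,0.0,0.32,0.0,0.0,30.16,0.32,0.0,0.63,0.0,5.71,0.0,3.81,2.86,2.86,3.49,2.54,0.32,1.27,1.0,0.0,0.32,0.0,0.5,0.0,0.0
BAL-2,13.61,0.95,0.63,0.0,1.27,0.32,0.0,6.01,1.27,0.63,2.22,0.32,10.13,0.0,6.65,0.63,6.01,1.58,1.9,0.63,2.53,0.0,0.0,0.63,0.0,0.0,0.0,0.0
SF-7,0.0,0.0,4.22,0.0,3.57,1.95,1.62,0.0,0.32,0.65,0.32,0.32,3.25,0.65,1.95,2.92,4.55,0.0,1.62,13.31,9.74,0.0,0.65,1.95,0.0,0.0,0.0,13.64
SF-13,0.0,0.6,7.85,3.02,3.02,1.51,3.32,0.6,3.02,0.0,0.3,5.14,1.51,0.6,2.42,2.72,0.6,0.0,2.42,8.46,6.34,1.0,0.0,2.42,0.3,12.99,0.0,0.0
SC-33,0.0,0.0,1.93,2.25,0.0,0.0,0.32,0.0,33.44,5.14,0.64,0.0,0.0,0.32,0.64,19.61,2.57,2.89,0.0,3.22,0.64,0.32,13.18,0.64,0.0,0.64,0.0,0.0
SC-35,0.0,0.0,0.34,0.34,0.0,0.0,0.0,0.0,33.9,5.48,3.08,8.22,0.0,0.0,0.0,36.64,0.0,0.34,0.0,0.0,0.0,0.0,10.27,0.0,0.0,0.0,0.0,0.0
SC-48,0.0,0.59,0.29,0.59,0.0,0.29,0.29,9.73,24.78,1.77,1.18,6.49,0.0,1.18,0.29,30.09,0.0,0.0,0.0,0.29,0.29,0.0,4.72,0.0,2.06,2.0,0.0,0.0
ES-59,0.0,0.0,5.04,2.97,2.08,1.78,0.59,0.89,11.87,0.0,11.28,1.48,5.04,0.0,1.78,0.0,5.93,1.48,1.48,4.15,2.08,0.0,0.0,2.08,0.0,0.0,0.0,5.64
ES-63,0.66,3.29,9.54,1.97,4.28,0.33,2.96,0.66,3.95,0.0,0.0,1.32,0.66,0.99,0.66,25.0,0.33,0.99,1.64,3.62,1.64,0.0,0.99,6.25,0.0,0.0,1.64,0.0
FL-96,0.0,0.0,0.0,0.0,0.0,0.0,7.37,5.77,0.64,0.0,0.0,0.0,0.0,3.21,0.0,75.0,0.0,0.64,0.0,0.32,0.0,0.0,2.88,0.0,0.32,0.0,0.0,0.0
FL-97,0.0,0.0,0.0,0.32,0.0,0.32,14.56,6.33,1.58,5.06,0.32,0.63,0.0,0.0,0.0,63.92,0.0,0.0,0.0,0.0,0.0,0.0,1.58,0.0,0.0,0.0,0.0,0.0
FL-102,0.0,0.0,0.0,0.89,0.0,0.0,11.61,3.27,4.46,6.25,1.19,2.98,0.0,1.79,0.0,52.68,0.0,0.3,0.0,0.3,0.3,0.0,2.68,0.0,0.3,1.0,0.0,0.0
FL-105,0.0,0.0,0.0,0.0,0.0,0.0,4.1,0.0,3.41,0.0,0.0,0.0,0.0,0.0,0.0,84.3,0.0,0.0,0.0,0.0,0.0,0.0,7.51,0.0,0.0,0.0,0.0,0.0
FL-117,0.0,0.32,0.64,0.0,0.0,0.96,24.36,13.78,3.85,2.24,0.0,0.32,0.0,0.0,1.6,34.62,0.64,0.32,0.96,2.88,0.32,0.0,0.96,0.0,0.0,0.64,0.0,0.0
IS_EB-121,0.0,1.85,4.32,0.93,2.78,1.85,0.0,1.85,33.02,0.31,4.01,3.09,0.0,0.62,0.0,0.31,1.23,1.54,1.85,6.79,0.62,0.0,0.0,0.93,0.31,0.0,3.4,0.0
IS_EB-145,0.0,0.28,4.26,0.28,1.14,0.85,5.11,2.84,12.78,0.0,0.0,0.57,0.28,2.27,0.57,0.57,3.69,1.42,0.57,4.26,0.28,0.0,0.28,0.28,3.69,0.0,12.5,0.0
IS_EB-148,0.0,0.0,5.67,0.42,2.1,1.47,2.31,3.78,0.63,0.63,0.21,0.0,0.0,5.25,0.63,3.99,1.26,0.84,0.0,1.26,2.94,0.0,0.0,0.0,7.77,0.0,12.39,0.0
IS_UB-149,0.0,0.0,4.91,0.92,0.92,1.23,1.23,2.45,20.86,0.0,0.0,0.0,0.0,0.31,0.92,3.68,1.23,7.98,0.92,2.76,6.75,0.0,0.0,2.76,0.92,0.0,0.0,0.0
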