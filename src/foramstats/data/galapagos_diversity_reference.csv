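sample_id,S,N,fisher_alpha,foram_index
DAR-B-43,57,318,19.19,4.16
BAL-1,53,315,18.24,2.22
BAL-2,60,316,21.39,2.58
SF-7,53,308,17.93,2.23
SF-13,48,331,14.51,1.87
SC-33,37,310,10.95,1.57
SC-35,12,292,2.52,1.44
SC-48,30,339,7.94,1.40
ES-59,52,337,16.23,1.65
ES-63,48,304,15.07,1.99
FL-96,15,312,3.29,1.72
FL-97,20,316,4.75,1.45
FL-102,31,336,8.33,1.44
FL-105,6,293,1.07,1.92
FL-117,30,312,7.81,1.18
IS_EB-121,48,329,15.47,1.63
IS_EB-145,52,352,16.85,1.61
IS_EB-148,47,475,12.95,1.72
IS_UB-149,48,317,15.25,1.71
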