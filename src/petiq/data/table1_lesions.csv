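lesion_id,size_group,tumor_type,beta100,beta200,beta300,beta400,beta500,osem
small_01,small,primary_rectal,14.62,14.05,13.5,13.05,12.63,10.94
small_02,small,primary_rectal,33.66,32.93,32.29,31.7,31.16,28.24
small_03,small,primary_rectal,26.59,25.73,24.97,24.24,23.55,19.91
small_04,small,primary_rectal,33.85,32.94,32.16,31.41,30.71,26.34
small_05,small,primary_rectal,33.2,30.52,28.26,26.26,24.49,19.87
small_06,small,primary_rectal,19.71,19.17,18.65,18.16,17.7,15.57
small_07,small,primary_rectal,16.6,16,15.4,14.82,14.29,14.26
small_08,small,lung_metastasis,36.4,35.88,35.36,34.83,34.31,30.98
small_09,small,lung_metastasis,26.29,25.62,24.99,24.37,23.78,22.29
small_10,small,lung_metastasis,11.35,10.96,11.71,10.57,10.21,9.11
small_11,small,lung_metastasis,12.05,11.59,12.48,11.14,10.74,9.72
small_12,small,lung_metastasis,13.61,12.59,14.88,11.75,11.04,9.18
small_13,small,lung_metastasis,18.59,16.93,20.68,15.62,14.58,12.85
small_14,small,lung_metastasis,17.56,17.35,17.12,16.86,16.59,15.5
small_15,small,lung_metastasis,17.37,16.74,16.21,15.74,15.34,14.01
small_16,small,pelvic_metastasis,12.27,12.01,11.74,11.49,11.22,10.29
small_17,small,pelvic_metastasis,14.054,13.82,13.59,13.37,13.14,12.29
small_18,small,pelvic_metastasis,19.86,17.69,15.8,14.27,13.017,10.04
small_19,small,pelvic_metastasis,18.4,17.71,16.32,15.78,15.25,13.16
small_20,small,pelvic_metastasis,13.92,13.62,12.65,12.24,11.88,11.02
small_21,small,pelvic_metastasis,21.52,18.42,17.74,17.39,17.01,16.33
small_22,small,pelvic_metastasis,23.08,21.07,19.75,18.78,18.43,17.55
small_23,small,pelvic_metastasis,25.32,22.34,21.27,20.73,20.27,18.67
small_24,small,pelvic_metastasis,19.39,16.78,15.43,14.25,13.2,11.42
small_25,small,pelvic_metastasis,14.92,14.65,14.25,13.79,13.46,12.31
small_26,small,pelvic_metastasis,17.05,14.1,12.59,11.68,10.87,11.22
small_27,small,pelvic_metastasis,40.26,38.34,36.77,35.48,34.22,27.96
large_01,large,primary_rectal,30.71,30.27,29.84,29.45,29.07,29.59
large_02,large,primary_rectal,21.92,21.4,21.02,20.72,20.46,20.78
large_03,large,primary_rectal,34.89,34.08,33.35,32.67,32.04,31.56
large_04,large,primary_rectal,30.22,29.79,29.42,29.1,28.81,27.5
large_05,large,primary_rectal,27.51,27.29,27.06,26.86,26.66,25.77
large_06,large,primary_rectal,8.99,8.87,8.78,8.67,8.51,7.34
large_07,large,primary_rectal,9.06,8.94,8.84,8.74,8.62,8.28
large_08,large,primary_rectal,8.22,7.91,7.28,6.98,6.88,6.23
large_09,large,lung_metastasis,17.36,17.83,17.3,17.27,17.24,16.62
large_10,large,lung_metastasis,18.05,18.27,17.8,17.55,17.31,16.51
large_11,large,lung_metastasis,43.14,42.06,41.41,40.99,40.7,38.29
large_12,large,lung_metastasis,22.7,20.23,19.35,18.65,18.06,19.85
large_13,large,pelvic_metastasis,15.79,14.29,13.35,12.65,12.12,14.16
large_14,large,pelvic_metastasis,32.43,28.86,26.9,26.17,25.44,26.89
large_15,large,pelvic_metastasis,26.21,23.14,21.69,20.67,19.87,19.5
large_16,large,pelvic_metastasis,36.17,35.03,34.08,33.26,32.44,30.64
large_17,large,pelvic_metastasis,10.06,8.7,8.042,7.6,7.26,6.31
large_18,large,pelvic_metastasis,16.39,12.39,10.53,9.58,8.92,8.55
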