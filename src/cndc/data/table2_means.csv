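variety,season,year,stage,n_rate,replicate,ldm,pnc,yield,ldm_se,pnc_se,sig_letter,pnc_sig_letter
Zhongjiazao 17,early,,TS,0,,0.49,3.20,,0.03,0.13,c,c
Zhongjiazao 17,early,,TS,75,,0.75,3.46,,0.32,0.04,b,b
Zhongjiazao 17,early,,TS,150,,0.79,3.78,,0.08,0.06,b,a
Zhongjiazao 17,early,,TS,225,,0.81,3.76,,0.01,0.10,a,a
Zhongjiazao 17,early,,JS,0,,0.82,1.80,,0.09,0.23,d,d
Zhongjiazao 17,early,,JS,75,,0.97,2.03,,0.18,0.05,c,c
Zhongjiazao 17,early,,JS,150,,1.03,2.30,,0.11,0.05,b,b
Zhongjiazao 17,early,,JS,225,,1.48,2.74,,0.10,0.26,a,a
Zhongjiazao 17,early,,BS,0,,1.18,1.55,,0.16,0.34,d,c
Zhongjiazao 17,early,,BS,75,,1.58,1.42,,0.11,0.09,c,c
Zhongjiazao 17,early,,BS,150,,1.85,1.86,,0.23,0.31,b,a
Zhongjiazao 17,early,,BS,225,,1.95,1.77,,0.02,0.32,a,b
Zhongjiazao 17,early,,HS,0,,1.44,0.94,,0.27,0.12,d,c
Zhongjiazao 17,early,,HS,75,,1.99,1.41,,0.08,0.56,c,a
Zhongjiazao 17,early,,HS,150,,2.25,1.48,,0.35,0.58,b,a
Zhongjiazao 17,early,,HS,225,,2.48,1.36,,0.15,0.17,a,b
Zhongjiazao 17,early,,FHS,0,,1.08,0.74,,0.05,0.06,d,d
Zhongjiazao 17,early,,FHS,75,,1.59,0.74,,0.18,0.06,c,c
Zhongjiazao 17,early,,FHS,150,,2.04,0.91,,0.17,0.04,b,b
Zhongjiazao 17,early,,FHS,225,,2.29,1.24,,0.15,0.05,a,a
Changliangyou 173,early,,TS,0,,0.49,3.32,,0.11,0.45,d,b
Changliangyou 173,early,,TS,75,,0.51,3.96,,0.10,0.05,c,a
Changliangyou 173,early,,TS,150,,0.67,3.36,,0.06,0.91,b,b
Changliangyou 173,early,,TS,225,,0.82,3.95,,0.05,0.23,a,a
Changliangyou 173,early,,JS,0,,0.79,1.75,,0.15,0.06,b,d
Changliangyou 173,early,,JS,75,,1.02,1.88,,0.10,0.29,b,c
Changliangyou 173,early,,JS,150,,1.26,2.53,,0.03,0.09,a,a
Changliangyou 173,early,,JS,225,,1.31,2.33,,0.04,0.07,a,b
Changliangyou 173,early,,BS,0,,1.35,1.42,,0.01,0.11,d,d
Changliangyou 173,early,,BS,75,,1.65,1.66,,0.15,0.25,c,c
Changliangyou 173,early,,BS,150,,2.04,1.77,,0.15,0.17,a,b
Changliangyou 173,early,,BS,225,,2.19,2.18,,0.03,0.13,b,a
Changliangyou 173,early,,HS,0,,1.62,1.09,,0.04,0.18,d,c
Changliangyou 173,early,,HS,75,,1.92,1.36,,0.28,0.11,c,b
Changliangyou 173,early,,HS,150,,2.44,1.63,,0.32,0.24,b,a
Changliangyou 173,early,,HS,225,,2.55,1.60,,0.14,0.37,a,a
Changliangyou 173,early,,FHS,0,,1.31,0.68,,0.13,0.07,c,d
Changliangyou 173,early,,FHS,75,,1.53,0.83,,0.20,0.04,b,c
Changliangyou 173,early,,FHS,150,,2.33,1.04,,0.34,0.08,a,b
Changliangyou 173,early,,FHS,225,,2.43,1.36,,0.08,0.31,a,a
Fumeizhan,late,,TS,0,,1.12,2.41,,0.12,0.10,d,d
Fumeizhan,late,,TS,90,,1.33,2.56,,0.28,0.06,c,c
Fumeizhan,late,,TS,180,,1.61,2.65,,0.15,0.07,b,b
Fumeizhan,late,,TS,270,,1.93,3.06,,0.09,0.48,a,a
Fumeizhan,late,,JS,0,,1.54,1.86,,0.01,0.06,d,c
Fumeizhan,late,,JS,90,,2.13,2.15,,0.07,0.06,c,b
Fumeizhan,late,,JS,180,,2.25,2.09,,0.01,0.15,b,a
Fumeizhan,late,,JS,270,,2.59,2.02,,0.10,0.23,a,a
Fumeizhan,late,,BS,0,,2.20,1.14,,0.26,0.11,c,d
Fumeizhan,late,,BS,90,,2.75,1.58,,0.12,0.09,a,c
Fumeizhan,late,,BS,180,,2.82,1.74,,0.09,0.03,a,b
Fumeizhan,late,,BS,270,,3.38,1.87,,0.33,0.02,b,a
Fumeizhan,late,,HS,0,,2.52,0.98,,0.16,0.09,b,d
Fumeizhan,late,,HS,90,,2.94,1.19,,0.06,0.08,c,c
Fumeizhan,late,,HS,180,,3.37,1.33,,0.08,0.03,b,b
Fumeizhan,late,,HS,270,,3.68,1.44,,0.05,0.04,a,a
Fumeizhan,late,,FHS,0,,1.96,0.79,,0.15,0.00,d,d
Fumeizhan,late,,FHS,90,,2.60,1.03,,0.15,0.05,c,c
Fumeizhan,late,,FHS,180,,2.93,1.19,,0.02,0.03,b,b
Fumeizhan,late,,FHS,270,,3.32,1.33,,0.04,0.03,a,a
Taiyouhang 1573,late,,TS,0,,1.22,2.25,,0.06,0.06,d,c
Taiyouhang 1573,late,,TS,90,,1.38,2.46,,0.14,0.01,c,b
Taiyouhang 1573,late,,TS,180,,1.81,2.84,,0.09,0.29,b,b
Taiyouhang 1573,late,,TS,270,,2.13,3.35,,0.11,0.08,a,a
Taiyouhang 1573,late,,JS,0,,1.99,1.40,,0.15,0.06,d,c
Taiyouhang 1573,late,,JS,90,,2.24,1.72,,0.19,0.07,c,a
Taiyouhang 1573,late,,JS,180,,2.28,1.69,,0.05,0.00,b,b
Taiyouhang 1573,late,,JS,270,,2.73,1.94,,0.22,0.22,a,a
Taiyouhang 1573,late,,BS,0,,2.26,1.23,,0.16,0.02,c,c
Taiyouhang 1573,late,,BS,90,,2.81,1.52,,0.17,0.03,b,b
Taiyouhang 1573,late,,BS,180,,2.96,1.72,,0.11,0.11,a,b
Taiyouhang 1573,late,,BS,270,,2.96,1.84,,0.26,0.10,a,a
Taiyouhang 1573,late,,HS,0,,2.98,1.07,,0.07,0.06,c,b
Taiyouhang 1573,late,,HS,90,,3.20,1.25,,0.09,0.01,b,b
Taiyouhang 1573,late,,HS,180,,3.39,1.42,,0.04,0.03,a,a
Taiyouhang 1573,late,,HS,270,,3.39,1.56,,0.04,0.03,a,a
Taiyouhang 1573,late,,FHS,0,,1.95,0.80,,0.07,0.04,d,b
Taiyouhang 1573,late,,FHS,90,,2.44,0.96,,0.06,0.04,c,b
Taiyouhang 1573,late,,FHS,180,,3.02,1.16,,0.16,0.09,b,a
Taiyouhang 1573,late,,FHS,270,,3.29,1.38,,0.08,0.06,a,a
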