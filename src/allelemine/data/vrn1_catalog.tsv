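name	deletion_start	deletion_end
VRN1-wild
VRN1-1	4200	9354
VRN1-2	4300	5200
VRN1-3	4400	6000
VRN1-4	4500	8500
VRN1-5	4700	5300
VRN1-6	4900	6100
VRN1-7	5100	5800
VRN1-8	5300	7500
VRN1-9	5500	6600
VRN1-10	5700	8000
VRN1-11	3500	11781
VRN1-12	6850	6926
VRN1-13	3000	3800
VRN1-14	3100	4600
VRN1-15	4600	11619
VRN1-16	3300	3560
VRN1-17	6000	6500
VRN1-18	7000	9950
VRN1-19	6820	6845
VRN1-20	6900	7029
VRN1-21	2400	2900
VRN1-22	2500	3200
VRN1-23	6750	6790
VRN1-24	9500	10200
VRN1-25	3000	3080
VRN1-25	9700	11000
VRN1-26	6960	7060
VRN1-27	2700	11604
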