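generation,region,surface_area_cm2,elf_volume_ml,epithelium_volume_ml,subepithelium_volume_ml,mucociliary_rate_per_h,blood_flow_ml_per_h
1,tracheobronchial,1.60221225,0.00160221,0.00480664,0.00801106,3.0,3.53748893
2,tracheobronchial,1.73038923,0.00155434,0.00475331,0.0077717,2.25,3.45671093
3,tracheobronchial,1.86882037,0.0015079,0.00470058,0.00753948,1.6875,3.37807006
4,tracheobronchial,2.018326,0.00146284,0.00464843,0.00731421,1.265625,3.30150554
5,tracheobronchial,2.17979208,0.00141913,0.00459686,0.00709566,0.94921875,3.22695835
6,tracheobronchial,2.35417545,0.00137673,0.00454586,0.00688365,0.71191406,3.15437122
7,tracheobronchial,2.54250948,0.00133559,0.00449543,0.00667797,0.53393555,3.08368855
8,tracheobronchial,2.74591024,0.00129569,0.00444556,0.00647844,0.40045166,3.01485637
9,tracheobronchial,2.96558306,0.00125697,0.00439624,0.00628487,0.30033875,2.94782229
10,tracheobronchial,3.20282971,0.00121942,0.00434747,0.00609708,0.22525406,2.88253545
11,tracheobronchial,3.45905608,0.00118298,0.00429924,0.0059149,0.16894054,2.81894648
12,tracheobronchial,3.73578057,0.00114763,0.00425154,0.00573817,0.12670541,2.75700746
13,tracheobronchial,4.03464302,0.00111334,0.00420437,0.00556672,0.09502906,2.69667185
14,tracheobronchial,4.35741446,0.00108008,0.00415773,0.00540039,0.07127179,2.6378945
15,tracheobronchial,4.70600762,0.00104781,0.0041116,0.00523903,0.05345384,2.58063156
16,tracheobronchial,5.08248822,0.0010165,0.00406599,0.00508249,0.04009038,2.52484045
17,alveolar,15.68627451,0.00031373,0.00078431,0.00156863,0.0,18.82352941
18,alveolar,31.37254902,0.00062745,0.00156863,0.00313725,0.0,37.64705882
19,alveolar,62.74509804,0.0012549,0.00313725,0.00627451,0.0,75.29411765
20,alveolar,125.49019608,0.0025098,0.00627451,0.01254902,0.0,150.58823529
21,alveolar,250.98039216,0.00501961,0.01254902,0.02509804,0.0,301.17647059
22,alveolar,501.96078431,0.01003922,0.02509804,0.05019608,0.0,602.35294118
23,alveolar,1003.92156863,0.02007843,0.05019608,0.10039216,0.0,1204.70588235
24,alveolar,2007.84313725,0.04015686,0.10039216,0.20078431,0.0,2409.41176471
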