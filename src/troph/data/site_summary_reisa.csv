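site,prey_diversity,prey_abundance,density_bullhead,density_salmon,density_trout,density_charr,density_total,levins_bullhead,levins_salmon,one_minus_is_bullhead_mean,one_minus_is_bullhead_sd,one_minus_is_salmon_mean,one_minus_is_salmon_sd,surface_bullhead,surface_salmon,overlap_total,overlap_aquatic,n_bullhead,n_salmon
SS1,0.74,393.2,36.6,5.3,0,0,41.90,3.0,5.8,0.54,0.17,0.47,0.04,0,0,54.9,54.9,37,9
SS2,0.94,304,35.1,2.5,0,1.53,39.13,5.3,2.2,0.64,0.18,0.42,0.22,0,65,11.5,44.0,69,8
SS3,0.78,82.2,1.9,8.9,1.14,0,11.94,5.9,9.0,0.59,0.11,0.50,0.08,0,11.7,31.7,37.5,5,16
SS4,0.50,95.3,20,2.9,0.70,0,23.60,4.2,5.6,0.62,0.17,0.64,0.23,4.6,6,62.5,65.4,57,12
SS5,0.70,63.6,28.6,0.001,0,0,28.60,4.8,4.1,0.61,0.16,0.54,0.13,9.5,42.5,31.6,57.4,32,13
SS6,0.98,83.3,22.6,0.001,0,0,22.60,6.9,6.6,0.80,0.10,0.75,0.09,1.8,0,33.5,34.4,32,9
SS7,0.67,120.1,0.9,16.3,5.70,0.79,23.73,3.9,4.3,0.49,0.16,0.58,0.17,0,0,34.4,35.5,9,61
SS8,0.75,123.1,19.4,3.9,4.96,5.86,34.10,5.8,5.4,0.69,0.14,0.61,0.13,0,0,44.6,44.6,43,20
SS9,0.77,63.6,2.8,8.9,4.61,0.82,17.14,6.8,2.8,0.76,0.12,0.46,0.16,0.9,0,33.2,33.6,17,10
SS10,0.79,144.6,18.4,4.4,1.90,4.43,29.13,5.3,1.9,0.66,0.13,0.45,0.21,0.2,20,41.3,51.4,29,7
SS11,0.90,77.9,2,3.9,3.82,1.27,10.99,6.2,3.6,0.64,0.13,0.63,0.06,0,30,25.3,40.3,11,14
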