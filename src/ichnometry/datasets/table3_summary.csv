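morphotype,FL_mean,FL_sd,FI_mean,FI_sd,stature_mean,stature_sd,mass_a_mean,mass_a_sd,mass_b_mean,mass_b_sd,mass_c_mean,mass_c_sd,age
1,13.55,0.49,0.48,0.01,87.93,3.20,12.64,0.79,,,,,<3
2,17,,0.41,0.02,110.32,,19.5,,,,,,5–6
3,20.83,0.51,0.38,0.03,135.19,3.33,31.66,2.05,,,,,8–11
4,22.80,0.42,0.38,0.01,147.96,2.75,,,46.21,0.77,48.76,2.23,>14 - adult
5,25.73,0.45,0.41,0.02,166.99,2.93,,,51.54,0.82,,,>14 - adult
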