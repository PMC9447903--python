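id,sex,age_y,body_mass_kg,height_cm,training_h_per_week,f_iso_N,f_iso_N_per_kg,sprint_v_mean_ms,sprint_v_max_ms,sprint_po_mean_W,sprint_po_mean_W_per_kg,sprint_po_max_W,sprint_po_max_W_per_kg,p30_est_W,p30_meas_W,delta_p30_pct,p30_meas_W_per_kg,want_p5_W,want_po_max_W,want_rf_pct,want_v_mean_ms,want_v_max_ms,popeak_est_W,popeak_meas_W,delta_popeak_pct,popeak_meas_W_per_kg,gxt_duration_s,hr_peak_bpm,rpe_central,rpe_peripheral,rpe_overall
1,F,22,63,163,4,129,2.1,2.1,2.7,45,0.7,350,5.6,55,55,1,0.9,63,366,17,1.9,2.2,43,41,-5,0.7,600,169,7,9,8
2,F,23,68,170,3,158,2.3,2.1,2.9,54,0.8,500,7.4,68,63,-8,0.9,81,473,49,1.8,2.3,50,38,-23,0.6,420,168,8,10,9
3,F,24,68,172,2,178,2.6,2.4,3.1,61,0.9,579,8.5,79,79,-1,1.2,96,534,33,1.9,2.4,61,44,-28,0.7,450,181,7,9,8
4,M,23,94,189,6,344,3.7,2.8,3.3,85,0.9,1092,11.6,160,125,-22,1.3,166,857,33,1.6,2.2,95,81,-15,0.9,540,178,7,8,8
5,M,28,76,176,5,,,3.0,3.5,84,1.1,792,10.4,,136,,1.8,176,864,40,1.7,2.4,,,,,,,,,
6,F,21,71,184,8,152,2.1,2.5,3.4,69,1.0,535,7.5,65,67,4,1.0,87,525,49,2.0,2.5,53,55,4,0.8,600,166,10,9,10
7,F,24,67,172,4,202,3.0,2.3,2.7,48,0.7,508,7.6,91,78,-14,1.2,112,466,48,1.7,2.2,,,,,,,,,
8,M,24,75,178,3,220,2.9,2.5,3.1,62,0.8,612,8.2,98,91,-7,1.2,121,656,48,1.8,2.5,70,57,-18,0.8,480,186,6,8,7
9,F,19,62,170,6,139,2.2,2.8,3.3,61,1.0,429,6.9,60,59,-1,1.0,98,438,58,1.9,2.6,47,44,-7,0.7,600,187,5,8,7
10,M,23,75,186,4,293,3.9,3.1,4.3,104,1.4,1027,13.7,136,172,26,2.3,162,990,15,2.5,3.01,123,113,-8,1.5,540,192,7,9,8
11,F,23,56,164,3,153,2.7,2.6,3.3,55,1.0,399,7.1,68,66,-2,1.2,86,380,40,1.9,2.3,50,56,11,1.0,720,187,7,8,8
12,F,21,60,169,12,216,3.6,2.8,3.2,57,0.9,376,6.3,99,87,-12,1.5,106,417,37,1.8,2.2,65,64,-2,1.1,660,175,7,10,9
13,M,23,96,191,12,341,3.6,3.0,3.8,117,1.2,1077,11.2,156,162,4,1.7,224,1058,47,2.0,2.7,,,,,,,,,
14,M,24,67,188,8,268,4.0,3.0,3.8,81,1.2,759,11.3,124,128,4,1.9,169,768,46,2.1,2.6,93,80,-14,1.2,540,187,6,9,8
15,M,25,81,188,3,184,2.3,2.2,2.8,54,0.7,581,7.2,79,68,-13,0.9,81,480,34,1.7,2.0,58,53,-9,0.7,570,186,8,7,8
16,F,20,55,163,4,132,2.4,2.1,2.9,43,0.8,355,6.5,58,58,-1,1.1,78,446,42,1.9,2.4,44,42,-5,0.8,540,181,8,9,9
17,M,22,80,191,5,322,4.0,3.0,3.8,94,1.2,789,9.9,150,150,0,1.9,161,736,23,2.0,2.5,110,83,-24,1.0,450,183,8,10,9
18,M,25,89,188,2,179,2.0,2.2,2.9,67,0.8,701,7.9,75,78,4,0.9,98,711,37,2.0,2.2,62,82,32,0.9,840,189,7,8,8
19,F,20,77,188,8,165,2.1,2.4,3.0,62,0.8,448,5.8,70,84,21,1.1,108,566,38,2.3,2.7,64,48,-25,0.6,420,171,8,9,9
20,M,23,69,179,5,293,4.3,3.0,3.8,87,1.3,670,9.7,136,125,-8,1.8,148,626,37,1.8,2.4,91,57,-37,0.8,420,166,7,9,8
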