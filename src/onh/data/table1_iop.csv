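primate_id,group,sex,age_years,eye,baseline_iop,baseline_iop_sd,n_injections,onset_weeks,iop_m2_7_mean,iop_m2_7_mean_sd,iop_m2_7_max,iop_m2_7_max_sd
3914,1,Female,9,OD,16.0,0.5,5,4,46.0,16.9,59.0,20.1
3914,1,Female,9,OS,14.0,1.0,5,4,24.0,1.9,27.0,3.1
5186,1,Female,9,OD,10.0,0.9,7,6,40.0,14.3,51.0,21.3
5186,1,Female,9,OS,10.0,1.2,7,6,15.0,1.5,18.0,1.9
5187,1,Female,9,OD,9.0,0.4,7,6,32.0,18.3,44.0,24.7
5187,1,Female,9,OS,9.0,0.4,7,6,15.0,1.4,17.0,1.9
5189,1,Female,9,OD,10.0,0.6,8,7,47.0,16.6,55.0,18.8
5189,1,Female,9,OS,10.0,0.9,8,7,16.0,1.4,18.0,1.2
5191,1,Female,9,OD,9.0,0.5,6,5,53.0,16.0,61.0,19.8
5191,1,Female,9,OS,12.0,0.5,6,5,17.0,1.1,20.0,1.6
5192,1,Female,5,OD,12.0,1.0,6,5,38.0,18.7,49.0,16.7
5192,1,Female,5,OS,11.0,1.0,6,5,21.0,1.2,23.0,1.0
5194,1,Female,9,OD,13.0,0.5,7,6,41.0,13.6,49.0,20.2
5194,1,Female,9,OS,11.0,0.5,7,6,17.0,1.3,19.0,2.3
5195,1,Female,9,OD,12.0,0.6,6,5,43.0,18.2,54.0,17.3
5195,1,Female,9,OS,12.0,1.2,6,5,17.0,1.2,20.0,2.3
5234,1,Female,9,OD,15.0,0.6,5,4,38.0,14.1,53.0,17.3
5234,1,Female,9,OS,14.0,0.6,5,4,17.0,1.0,19.0,0.6
5235,1,Female,9,OD,14.0,0.6,6,5,50.0,15.2,61.0,16.2
5235,1,Female,9,OS,16.0,0.6,6,5,19.0,1.4,20.0,0.8
2677,2,Female,5,OD,13.0,1.2,6,5,26.0,11.5,33.0,8.3
2677,2,Female,5,OS,15.0,1.7,6,5,24.0,9.2,38.0,10.8
2705,2,Female,5,OD,16.0,1.7,6,5,29.0,10.7,27.0,7.2
2705,2,Female,5,OS,15.0,2.3,6,5,23.0,6.7,39.0,10.5
5407,2,Female,5,OD,14.0,1.9,3,2,35.0,21.0,46.0,21.5
5407,2,Female,5,OS,12.0,1.7,3,2,37.0,16.3,50.0,16.4
5408,2,Female,5,OD,15.0,0.5,6,5,32.0,10.5,38.0,9.3
5408,2,Female,5,OS,14.0,0.6,6,5,32.0,10.9,37.0,12.2
2873,2,Male,4,OD,16.0,2.9,6,5,31.0,15.6,53.0,16.9
2873,2,Male,4,OS,17.0,2.1,6,5,38.0,17.1,41.0,15.1
2874,2,Male,4,OD,12.0,2.3,5,4,33.0,13.9,39.0,11.5
2874,2,Male,4,OS,16.0,1.0,5,4,32.0,10.3,41.0,15.4
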