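primate_id,group,eye,timepoint,mrw,mrw_sd,lcd,lcd_sd
3914,1,OD,baseline,257.2,85.8,247.5,20.3
3914,1,OD,month7,111.4,28.3,460.5,44.9
3914,1,OS,baseline,239.8,92.2,248.1,9.71
3914,1,OS,month7,254.7,50.2,250.3,9.5
5186,1,OD,baseline,317.9,115.4,152.6,7.7
5186,1,OD,month7,110.3,40.1,207.7,17.9
5186,1,OS,baseline,306.4,108.2,159.8,16.3
5186,1,OS,month7,299.6,39.8,147.7,18.2
5187,1,OD,baseline,305.0,101.5,202.3,14.5
5187,1,OD,month7,224.5,48.5,338.7,34.1
5187,1,OS,baseline,312.4,105.7,197.4,13.0
5187,1,OS,month7,316.7,50.4,195.6,12.1
5189,1,OD,baseline,271.3,107.1,138.0,14.1
5189,1,OD,month7,257.7,48.0,219.8,20.4
5189,1,OS,baseline,264.2,97.7,162.7,18.3
5189,1,OS,month7,276.6,48.5,171.3,24.9
5191,1,OD,baseline,192.4,99.1,275.0,6.4
5191,1,OD,month7,76.1,50.0,584.8,29.6
5191,1,OS,baseline,203.1,91.1,285.8,6.1
5191,1,OS,month7,208.1,45.9,272.4,12.8
5192,1,OD,baseline,325.2,90.8,188.3,13.3
5192,1,OD,month7,118.8,24.9,383.7,75.6
5192,1,OS,baseline,312.1,94.6,193.5,14.0
5192,1,OS,month7,326.8,44.8,183.8,18.3
5194,1,OD,baseline,277.2,111.6,235.3,19.0
5194,1,OD,month7,227.9,40.6,329.4,34.2
5194,1,OS,baseline,277.23,106.0,227.8,22.2
5194,1,OS,month7,268.6,52.5,220.9,17.9
5195,1,OD,baseline,276.5,90.9,217.7,10.4
5195,1,OD,month7,171.3,45.5,284.2,20.0
5195,1,OS,baseline,291.2,92.6,190.5,14.2
5195,1,OS,month7,298.4,40.9,181.7,21.3
5234,1,OD,baseline,309.2,91.7,158.3,16.4
5234,1,OD,month7,280.2,40.2,203.7,22.9
5234,1,OS,baseline,278.3,89.5,173.4,21.6
5234,1,OS,month7,373.95,37.1,164.6,19.1
5235,1,OD,baseline,256.1,92.3,215.5,9.3
5235,1,OD,month7,92.5,36.1,338.1,16.7
5235,1,OS,baseline,233.4,97.3,215.6,7.6
5235,1,OS,month7,265.6,52.3,192.3,8.3
2677,2,OD,baseline,292.6,43.6,200.7,29.3
2677,2,OD,month7,242.3,29.9,247.3,43.6
2677,2,OS,baseline,264.3,52.9,192.1,21.3
2677,2,OS,month7,208.7,48.3,250.2,39.5
2705,2,OD,baseline,293.4,57.3,213.7,33.5
2705,2,OD,month7,317.3,32.2,252.2,31.7
2705,2,OS,baseline,291.0,53.1,223.6,31.2
2705,2,OS,month7,270.9,49.7,257.4,32.7
5407,2,OD,baseline,304.7,57.4,236.4,6.7
5407,2,OD,month7,242.3,17.7,247.3,17.0
5407,2,OS,baseline,289.0,55.3,221.2,14.1
5407,2,OS,month7,208.7,35.3,250.2,20.4
5408,2,OD,baseline,277.0,47.6,221.4,21.4
5408,2,OD,month7,317.3,43.8,252.2,24.4
5408,2,OS,baseline,277.5,52.4,225.4,21.2
5408,2,OS,month7,270.9,52.2,257.35,16.1
2873,2,OD,baseline,341.1,66.6,193.0,33.6
2873,2,OD,month7,304.2,16.6,262.6,62.6
2873,2,OS,baseline,360.7,62.3,178.1,32.1
2873,2,OS,month7,182.1,54.3,302.3,46.5
2874,2,OD,baseline,366.2,46.8,197.7,9.2
2874,2,OD,month7,287.4,42.7,241.6,13.0
2874,2,OS,baseline,372.7,46.4,217.4,4.7
2874,2,OS,month7,259.2,4.0,248.6,21.4
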