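system,INT,INT_sd,ELE,ELE_sd,VDW,VDW_sd,GBSOL,GBSOL_sd,GBTOT,GBTOT_sd
dgFSH,7274.46,72.07,-13883.53,117.07,-1932.3,20.80,-4531.92,95.29,-13073.29,80.25
FSH15_NAG,7297.21,68.66,-13797.88,203.03,-1913.37,30.70,-4601.85,171.04,-13015.89,72.16
FSH24_NAG,7307.17,70.01,-13802.93,133.97,-1962.31,31.51,-4549.6,111.06,-13007.67,66.04
FSH15_TAG,7701.06,62.26,-12616.12,99.75,-2040.92,49.93,-4697.16,80.48,-11653.15,77.85
FSH24_TAG,8118.63,56.35,-10945.91,130.25,-2123.45,50.04,-5284.43,119.37,-10235.16,68.28
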