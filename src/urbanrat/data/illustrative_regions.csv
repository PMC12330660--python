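region,duration_s,frequency_hz
lab_22khz,0.3,19000
lab_22khz,3.5,19000
lab_22khz,3.5,26000
lab_22khz,0.3,26000
lab_50khz,0.01,35000
lab_50khz,0.15,35000
lab_50khz,0.15,80000
lab_50khz,0.01,80000
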