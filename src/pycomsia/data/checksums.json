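{
 "table4_predictions.csv": "6561fccbb14d93d27d9763893ea6d96351f25a5f95b08b59ec7114672780cfab",
 "table2_validation_reference.csv": "70d4d5af1493034e6e0ec82e04dc60d3f08dcc5a6334578055c691d97134cf90",
 "table1_combination_reference.csv": "5c2c69218c54ab0dd9d20b4e71f35f94dc17ce45ed0aeaf155b7de49ab509bb8"
}
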