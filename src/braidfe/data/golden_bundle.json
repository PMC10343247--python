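{
 "EL": 90.1071,
 "ET": 0.479452,
 "EZ": 0.479452,
 "vLT": 0.339,
 "GLT": 0.172316,
 "GLZ": 0.172316,
 "GTZ": 0.171314
}
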