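sa_id,successes,sampled
SA1,7,19
SA2,7,19
SA3,12,19
SA4,9,19
SA5,11,19
SA6,16,19
SA7,8,19
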