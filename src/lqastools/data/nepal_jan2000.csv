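sa_id,successes,sampled
SA1,7,19
SA2,9,19
SA3,14,19
SA4,13,19
SA5,17,19
SA6,19,19
SA7,12,19
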