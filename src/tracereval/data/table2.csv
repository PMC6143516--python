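patient_id,cavity_signal,margin_status
BC01,present,positive
BC02,present,positive
BC03,present,positive
BC04,present,positive
BC05,present,positive
BC06,present,positive
BC07,present,positive
BC08,present,negative
BC09,present,negative
BC10,absent,positive
BC11,absent,negative
BC12,absent,negative
BC13,absent,negative
BC14,absent,negative
BC15,absent,negative
BC16,absent,negative
BC17,absent,negative
BC18,absent,negative
BC19,absent,negative
BC20,absent,negative
BC21,absent,negative
BC22,absent,negative
BC23,absent,negative
BC24,absent,negative
BC25,absent,negative
BC26,absent,negative
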