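# scenario for the bundled toy network: uptake E1 fixed to 1 mmol gDW^-1 h^-1
reaction_id	lower	upper
E1	1.0	1.0
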