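mirna	mouse_dir	Bray	Mestdagh
miR-130b	Up	Up
miR-17	Up	Up
miR-18a	Up	Up	Up
miR-19a	Up	Up	Up
miR-19b	Up	Up
miR-20a	Up	Up	Up
miR-20b	Up	Up	Up
miR-25	Up	Up
miR-9	Up	Up	Up
miR-9*	Up	Up
miR-93	Up	Up
miR-323-3p	Up	Down
miR-369-5p	Up	Down
miR-410	Up	Down
miR-411	Up	Down
miR-433	Up	Down
miR-494	Up	Down
miR-152	Down	Down
miR-204	Down	Down
miR-26a	Down		Down
miR-26b	Down		Down
miR-30a	Down		Down
miR-30a*	Down	Down
miR-30d	Down		Down
miR-30e	Down		Down
miR-30e*	Down	Down
miR-328	Down	Down	Down
miR-491	Down	Down	Down
miR-130a	Down		Up
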