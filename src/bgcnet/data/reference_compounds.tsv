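name	formula	note
alteramide_a	C29H38N2O6	polycyclic tetramate macrolactam; yellow solid; broad-spectrum antibacterial
prodigiosin	C20H25N3O	red tripyrrole pigment of Serratia marcescens
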