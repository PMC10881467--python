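ucne	state	high_confidence	dnase_stages	scatac	marks
U1	sustained_adult	True	E89	GanglionPrecursors@FW13/14	H3K27ac:FW13/14,adult;H3K4me1:FW13/14
U2	marked	False	E89		H3K4me1:FW15/16
U3	none	False			
U4	open_only	False		Rods@FW23/24	
U5	none	False			
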