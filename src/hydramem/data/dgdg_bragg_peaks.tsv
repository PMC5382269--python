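# Measured Bragg peak positions of DGDG multilayers in excess D2O
# (neutron diffraction, lamellar h00 reflections; Gaussian fits on a
# constant background).  Columns: order h, q_x (1/angstrom), delta q_x.
1	0.11697	0.000130
2	0.23346	0.000103
3	0.34957	0.000302
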