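# Tabulated refractive-index decrements and imaginary parts.
name,energy_keV,delta,beta
PET,27.0,4.09e-7,7.83e-11
PEEK,27.0,3.92e-7,6.91e-11
water,9.7,2.46e-6,5.94e-9
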