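# Standard X-H neutron bond distances (Angstrom), keyed by the heavy element.
# Override per call or via config; e.g. sp3-primary C-H 1.083 can be set here.
C: 1.092
N: 1.009
O: 0.983
S: 1.338
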