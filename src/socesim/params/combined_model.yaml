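# Parameter overrides for the calcium subsystem embedded in the whole-cell
# membrane model: 300 ER-PM junctions and a tenfold IP3R flow rate.
geometry:
  n_junctions: 300
ip3r:
  R_ip3r: 1.8   # µM/s
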