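# Valence-state ionization potentials and electron affinities (eV) for
# 2p-pi orbitals, Hinze-Jaffe values as adopted in classic PPP practice.
# n_pi is the default number of pi electrons the center donates; two-electron
# donors carry the ionization potential of the corresponding positive
# valence state.  Slater exponents are derived from these values at load
# time (hydrogen-like relation), so every model parameter traces back to
# this table plus the single empirical constant C.
# key,element,n_pi,ip_ev,ea_ev
C,C,1,11.16,0.03
N1,N,1,14.12,1.78
N2,N,2,28.71,11.96
O1,O,1,17.70,2.47
O2,O,2,34.12,15.30
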