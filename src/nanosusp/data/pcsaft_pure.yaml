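# Pure-component PC-SAFT parameters for the fenofibrate/HPMC/water system.
#
# `as_printed` reproduces the published parameter table verbatim.  The
# printed fenofibrate row carries a zero dispersion energy (and a non-zero
# kappaAB with zero epsAB), which would null the dispersion term entirely;
# it is treated as a table defect.  `overrides` supplies working values and
# `supplements` adds fields the table does not print; every such entry
# carries a provenance note.
as_printed:
  fenofibrate: {m: 3.85, sigma_A: 4.76, eps_k_K: 0.0, epsAB_k_K: 0.0, kappaAB: 0.02}
  hpmc:        {m: 595.4, sigma_A: 2.88, eps_k_K: 298.0, epsAB_k_K: 1602.3, kappaAB: 0.02}
  water:       {m: 1.0, sigma_A: 3.0, eps_k_K: 366.0, epsAB_k_K: 2500.7, kappaAB: 0.035}

overrides:
  fenofibrate:
    eps_k_K: 250.0
    # provenance: estimate; literature-typical dispersion-energy magnitude
    # for a mid-size drug-like molecule.  The printed value (0 K) is
    # non-physical; the original literature parameterization is not
    # reproduced in the source table.
    epsAB_k_K: 0.0
    kappaAB: 0.0
    # provenance: fenofibrate has no hydrogen-bond donor and is treated as
    # non-self-associating; the printed kappaAB = 0.02 with epsAB = 0 is
    # inert anyway.

supplements:
  fenofibrate:
    n_sites: 0
    Mw: 360.831   # provenance: molecular formula C20H21ClO4
  hpmc:
    n_sites: 2    # provenance: 2B donor/acceptor scheme for the polymer
    Mw: 13000.0
    # provenance: estimate; Pharmacoat 603 (HPMC 2910, 3 mPa s grade)
    # number-average molar mass, not printed in the source.
  water:
    n_sites: 2    # provenance: 2B hydrogen-bonding scheme
    Mw: 18.015

# Association topology: hydrogen bonding channels actually switched on.
# Water self-association dominates (stabilizer mole fraction < 0.01, API
# non-associating); cross pairs can be enabled per entry.
assoc_pairs:
  - [water, water]
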