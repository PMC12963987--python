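# Nuclear decay data for the nuclides used by tatkit.
#
# Sources: ICRP Publication 107 / NNDC NuDat decay radiation listings.
# This file, not the code, is the authoritative source of the constants;
# edit it to use a different evaluation.
#
# half_life_days : physical half-life in days
# alpha_mev      : mean alpha energy emitted per decay of this nuclide (MeV),
#                  averaged over its decay modes
# electron_mev   : mean beta + conversion/Auger electron energy per decay (MeV)
#
# Photon energy is deliberately absent: for mouse-scale volumes photons are
# assumed to escape, so only alpha and electron energy is absorbed locally.
nuclides:
  In-111:
    half_life_days: 2.8047
    alpha_mev: 0.0
    electron_mev: 0.0345
  Ac-225:
    half_life_days: 9.920
    alpha_mev: 5.790
    electron_mev: 0.022
  Fr-221:
    half_life_days: 3.3333e-3      # 4.80 min
    alpha_mev: 6.303
    electron_mev: 0.010
  At-217:
    half_life_days: 3.7731e-7      # 32.6 ms
    alpha_mev: 7.066
    electron_mev: 0.0
  Bi-213:
    half_life_days: 3.1667e-2      # 45.6 min; 97.8% beta, 2.2% alpha
    alpha_mev: 0.129
    electron_mev: 0.425
  Po-213:
    half_life_days: 4.2824e-11     # 3.7 us
    alpha_mev: 8.376
    electron_mev: 0.0
  Tl-209:
    half_life_days: 1.5000e-3      # 2.16 min
    alpha_mev: 0.0
    electron_mev: 0.659
  Pb-209:
    half_life_days: 0.134583       # 3.23 h
    alpha_mev: 0.0
    electron_mev: 0.198
  Bi-209:
    half_life_days: .inf           # effectively stable
    alpha_mev: 0.0
    electron_mev: 0.0

chains:
  Ac-225:
    - {parent: Ac-225, child: Fr-221, fraction: 1.0}
    - {parent: Fr-221, child: At-217, fraction: 1.0}
    - {parent: At-217, child: Bi-213, fraction: 1.0}
    - {parent: Bi-213, child: Po-213, fraction: 0.978}
    - {parent: Bi-213, child: Tl-209, fraction: 0.022}
    - {parent: Po-213, child: Pb-209, fraction: 1.0}
    - {parent: Tl-209, child: Pb-209, fraction: 1.0}
    - {parent: Pb-209, child: Bi-209, fraction: 1.0}
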