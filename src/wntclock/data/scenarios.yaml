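# Builtin experiment configurations.  Loaded by wntclock.scenarios.builtin_scenarios().
# All concentrations nM, times min.  Seeds are fixed so every run is reproducible.

- name: reference_h3
  kind: timeseries
  description: >
    Reference oscillation at the default parameter set (Hill coefficient 3):
    sustained limit cycle with a period of roughly two hours.
  seed: 0
  overrides: {}
  duration: 6000.0
  transient: 2000.0

- name: hill2
  kind: placeholder
  description: >
    Hill-coefficient-2 variant.  Oscillating only with a much higher
    beta-catenin affinity for the GSK3beta-Axin complex; the matching
    parameter set is not bundled with the package, so this scenario fails
    with an explanatory message unless values are supplied.
  seed: 0
  overrides: null

- name: fig2_scans
  kind: scan_suite
  description: >
    Eight one-parameter sensitivity scans of the Dkk1 period and
    amplitude, spanning a factor of four either side of the reference
    value of each parameter.
  seed: 0
  overrides: {}
  scans:
    - {name: v,      lo: 0.95,    hi: 15.2,   n: 9}
    - {name: alpha,  lo: 0.55,    hi: 8.8,    n: 9}
    - {name: k_tx,   lo: 0.005,   hi: 0.08,   n: 9}
    - {name: S_A,    lo: 0.005,   hi: 0.08,   n: 9}
    - {name: k_tl,   lo: 0.00625, hi: 0.1,    n: 9}
    - {name: tau_D,  lo: 4.0,     hi: 64.0,   n: 9}
    - {name: K_GA,   lo: 0.375,   hi: 6.0,    n: 9}
    - {name: K_C,    lo: 2.0,     hi: 32.0,   n: 9}

- name: fig3_modifier_scan
  kind: modifier_scan
  description: >
    Static Wnt-level response: period and amplitude of Dkk1 for a range
    of constant multipliers on the LGA formation rate.
  seed: 0
  overrides: {}
  modifiers: [0.25, 0.35, 0.5, 0.7, 0.85, 1.0, 1.2, 1.5, 2.0, 2.8, 4.0]

- name: fig4_sync
  kind: elongation
  description: >
    Elongating embryo with neighbour-copy synchronization: cells bud
    every 10 min, inherit the anterior neighbour's state, and descend a
    fold-2 Gaussian Wnt gradient over a 1200-min transit.  The Dkk1
    series at the determination front oscillates at the clock period.
  seed: 0
  overrides: {}
  schedule: "gaussian:fold=2,transit=1200,target=k_LGA"
  elongation: {R: 10.0, T_transit: 1200.0, n_cells: 220, sync: copy_neighbor}

- name: fig4_identical
  kind: elongation
  description: >
    Control: every cell is assigned the same initial state, so the Dkk1
    level read out at the determination front is constant.
  seed: 0
  overrides: {}
  schedule: "gaussian:fold=2,transit=1200,target=k_LGA"
  elongation: {R: 10.0, T_transit: 1200.0, n_cells: 220, sync: identical}

- name: s3_jitter
  kind: elongation
  description: >
    Weak desynchronization: each newborn cell copies its neighbour with
    10% multiplicative jitter per species.  The front period is almost
    unaltered.
  seed: 11
  overrides: {}
  schedule: "gaussian:fold=2,transit=1200,target=k_LGA"
  elongation: {R: 10.0, T_transit: 1200.0, n_cells: 220, sync: jitter, jitter_eps: 0.1}

- name: s3_random
  kind: elongation
  description: >
    Strong desynchronization: each newborn cell is drawn uniformly from
    the limit-cycle range of every species.  No periodicity remains at
    the determination front.
  seed: 12
  overrides: {}
  schedule: "gaussian:fold=2,transit=1200,target=k_LGA"
  elongation: {R: 10.0, T_transit: 1200.0, n_cells: 220, sync: random_full}

- name: s4_decrease
  kind: elongation
  description: >
    Tail-bud Wnt downregulation: the birth-time modifier drifts linearly
    from 1.0 to 0.5 over the run, flattening the gradient; the front
    amplitude shrinks as segmentation winds down.
  seed: 0
  overrides: {}
  schedule: "gaussian:fold=2,transit=1200,target=k_LGA"
  elongation: {R: 10.0, T_transit: 1200.0, n_cells: 420, sync: copy_neighbor}
  drift: {start_level: 1.0, end_level: 0.5, t_start: 0.0, t_end: 4200.0}

- name: s4_increase
  kind: elongation
  description: >
    Tail-bud Wnt upregulation: the birth-time modifier drifts linearly
    from 1.0 to 10x reference over the run; the front period lengthens
    as the intrinsic clock slows at high Wnt.
  seed: 0
  overrides: {}
  schedule: "gaussian:fold=2,transit=1200,target=k_LGA"
  elongation: {R: 10.0, T_transit: 1200.0, n_cells: 420, sync: copy_neighbor}
  drift: {start_level: 1.0, end_level: 10.0, t_start: 0.0, t_end: 4200.0}
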