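# trifilament

A half-sarcomere force simulator in which three filaments matter: actin,
myosin and titin.  A 3-state cross-bridge distribution model (probability
densities over cross-bridge strain, advected by filament sliding) provides
active force; a stochastic titin chain — worm-like-chain segments for the
folded/unfolded immunoglobulin (IG) domains, an extensible WLC for the PEVK
segment, Monte-Carlo force-dependent IG-domain unfolding with no refolding —
provides passive force.  On activation titin can bind to the (rigid) actin
filament at the most proximal PEVK residue, shortening its free spring
length.  That single mechanism reproduces history-dependent phenomena that
cross-bridge models alone cannot: residual force enhancement after active
stretch, force depression after active shortening, passive force enhancement
after deactivation, and large activation-dependent forces at sarcomere
lengths beyond actin-myosin filament overlap.

## Layout

| module | contents |
| --- | --- |
| `trifilament.polymer` | WLC and extensible-WLC force laws with exact inverses |
| `trifilament.titin` | serial-compartment chain of one titin strand: equal-force solve, slack convention, calcium parameter set, actin binding |
| `trifilament.unfolding` | Bell-model unfolding kinetics, the Monte-Carlo strand ensemble, passive ensemble traces |
| `trifilament.crossbridge` | 3-state distribution model: algebraic steady state, upwind advection-reaction stepping, overlap geometry, active-force integral |
| `trifilament.protocols` | protocol engine (set length / activate / ramp / hold / deactivate), scenario flags, canonical experiment registry, enhancement/depression metrics |
| `trifilament.calibration` | four-region hysteresis classification, Levenberg-Marquardt region fits, synthetic loop generator |
| `trifilament.io_cli` + `trifilament.cli` | YAML config schema, trace CSV round trips, run manifests, the `trifilament` command |

Units: nm, pN, s, K; stress in nN/um^2 (= kPa).  Sarcomere lengths are in
um at the protocol level; the model simulates one half sarcomere (HSL in
nm, = sarcomere length x 500).

## CLI

```sh
trifilament protocols                      # list canonical protocols
trifilament simulate --protocol rfe --seed 1 --out trace.csv --metrics
trifilament simulate --protocol beyond-overlap-2.4 --strands 500 --out bo.csv
trifilament synth-data --seed 7 --out loop.csv          # synthetic hysteresis
trifilament calibrate --data loop.csv --out report.txt --config-out fitted.yaml
```

Canonical protocols: `beyond-overlap-2.4`, `beyond-overlap-3.4` (active
stretches past filament overlap, from optimal and from long length), `rfe`
(activate at 2.4 um, stretch to 3.0 um at 100 nm/s per sarcomere), `fd`
(passive stretch to 2.6 um, activate, shorten to 2.4 um), `pfe` (`rfe` plus
a 5 s deactivation).  Each has `/passive`, `/calcium-only` and
`/no-binding` variants (the last is the regular cross-bridge model plus
passive titin).  Scenario flags select the calcium-vs-binding ordering at
activation (`instantaneous-calcium` | `instantaneous-binding`) and the
unbinding behaviour at deactivation (`keep-bound` | `immediate-unbind`).

Every run writes a `<trace>.manifest.json` (config hash, seed, version,
event log); identical config + seed gives byte-identical outputs.

Configuration is a single YAML file; every tunable has a documented default
in `trifilament.io_cli.SCHEMA`, unknown keys are rejected.  Pass it with
`--config`.

## Caveats

Cross-bridge rate functions and the WLC/unfolding parameter values are
provisional defaults (configurable, and recoverable from data via
`trifilament calibrate`); quantitative magnitudes of the history-dependent
effects depend on them.  Multi-sarcomere non-uniformity, actin compliance
(documented as negligible via `titin.actin_extension`) and time-resolved
actin-titin attachment kinetics are out of scope.
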