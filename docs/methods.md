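# Methods

## Bird heat-transfer model

The flock's sensible heat production is computed from a steady
resistance network per unit of bird surface. Heat flows from the body
core (held at `Tb = 41 °C`, the normal deep-body temperature of
broilers) through tissue (`rt`), coat (`rc`) and air boundary layer
(`ra`) resistances; in parallel, the fraction `1 - R` of the body in
floor contact conducts through `rt + rflr`, the coat surface exchanges
long-wave radiation through `rr`, and two latent losses bypass the
sensible chain: skin evaporation `Ec` (leaves at the skin node) and
respiration `Er` (leaves the core directly). The two unknown node
temperatures `Ts` (skin) and `Tc` (coat surface) are fixed by the core
balance `Qt = R·Qc + Er + (1-R)·Qflr` and the coat-surface balance
`Qc = Qa + Qr`.

Two solvers share these equations:

* **Fixed-point sweep** (`solve_bird_temperatures`): start from the
  classic initial guess that splits the core-air difference into
  thirds (`Ts0 = Tb - (Tb-Ta)/3`, `Tc0 = Tb - 2(Tb-Ta)/3`), evaluate
  `Qc` and `Qt` at the current temperatures, update `Ts` from the
  tissue layer and `Tc` from the coat layer, repeat until both updates
  fall below `tol` (default 1e-6 °C, max 1000 sweeps). The plain sweep
  is *not* unconditionally stable: for realistic resistance sets the
  iteration matrix has an eigenvalue below −1 and the sweep oscillates
  divergently. The solver therefore estimates the dominant eigenvalue
  of the relaxed sweep from the correlation ratio `r` of successive
  raw updates and, on oscillation (`r < 0`), resets the relaxation
  factor to `ω/(1-r)` — the value that would annihilate that mode.
  This changes the path, never the fixed point. Non-convergence is
  reported in the result (`converged=False`, last residual), not
  raised.
* **Closed form** (`solve_bird_temperatures_direct`): with constant
  latent terms the system is linear in `(Ts, Tc)`; the 2×2 solve is
  exact and serves both as the test oracle for the iteration and as
  the fast route inside the zonal simulator (≈100× cheaper over the
  21,600 per-zone evaluations of a simulated hour; a config flag
  restores the iterative route).

An alternative grouping of the core balance, `Qt = R·(Qc + Er) +
(1-R)·Qflr` (respiration scaled by the exposed fraction), is available
behind the `respiration_exposed` flag in both solvers so the choice is
auditable; the default counts the full respiratory loss against the
core, matching the structure in which respiration is a direct
core-to-air path.

Flock-level source terms: `Sh = Ac·nb·Qa/Vz` (W m⁻³ of bird-zone air)
and quadratic drag `Su = -(nb·Ap·Cd/Vz)·½ρv²`.

### Parameter defaults

The resistances and latent losses are configuration, not constants of
the package; the defaults below are placeholders of the right order of
magnitude for ~3-week broilers and should be replaced when calibrated
values are available.

| parameter | default | units | note |
|---|---|---|---|
| `tb` | 41 | °C | deep-body temperature, fixed |
| `rt` | 0.10 | m² °C W⁻¹ | tissue |
| `rc` | 0.15 | m² °C W⁻¹ | coat |
| `ra` | `1/(4.2 + 9.0·v^0.6)` | m² °C W⁻¹ | mixed natural/forced convection |
| `rflr` | 0.30 | m² °C W⁻¹ | litter contact |
| `rr` | 0.18 | m² °C W⁻¹ | ≈ 1/(4εσT³) at house temperature |
| `ec` | 10 | W m⁻² | skin latent loss |
| `er` | 5 | W m⁻² | respiratory latent loss |
| `exposed` (R) | 0.8 | – | surface fraction exposed to air |
| `ac`, `ap` | 0.1, 0.05 | m² | surface / projected area |
| `cd` | 1.0 | – | bluff-body drag |
| `nb`, `vz` | 30,000, 587.25 | –, m³ | flock size, bird-zone volume |

With these defaults the model yields ≈33 W m⁻² sensible flux at
26.5 °C still air (≈99 kW flock total, ~3.3 W per bird), consistent
with mid-growout broiler heat production. The velocity-dependent `ra`
gives the wind-chill response: faster air extracts more sensible heat
from the birds. A constant `ra` may be supplied instead.

Note on node ordering: a large `Ec` with warm air can legitimately make
the coat surface warmer than the evaporatively cooled skin
(`Ts < Tc`); the chain `Ta ≤ Tc ≤ Ts ≤ Tb` is guaranteed only for
`Ec = 0`, and the property tests assert it under that condition.

## Ventilation components and operating point

* **Fans**: affine curve `Q(ΔP) = max(0, Q0 - k·ΔP)` with defaults
  `Q0 = 38,650 m³ h⁻¹`, `k = 588 m³ h⁻¹ Pa⁻¹` (free-air delivery just
  above the 37,000 m³ h⁻¹ rating of the reference fans, cutoff at
  ≈65.7 Pa). All curve constants are configuration.
* **Inlet baffles**: 29 per side, 0.3 m² each, sharp-edged-orifice law
  `Q_i = C_d·A_i·f_i·√(2ΔP/ρ)` with `C_d = 0.61`; a closed inlet
  passes nothing at any pressure. The CFD-facing momentum-blocking
  form `Su = -ρv/Δt` is kept as a documented primitive.
* **Cooling pads**: outlet temperature `Tdb - η·(Tdb - Twb)` with
  saturation efficiency `η = 0.7` (wet-bulb depression is the standard
  reference); airflow from the porous inertial resistance
  (23.3 m⁻¹ over 0.15 m thickness) converted to an equivalent-orifice
  law `v_face = √(2ΔP/(ρ·C₂·t))`, i.e. an effective discharge
  coefficient `1/√(C₂·t) ≈ 0.53` on the 48 m² face.
* **Circulation fans**: six ceiling units, constant 4.4 m s⁻¹ intake;
  in the zonal surrogate their effect is a lateral mixing exchange
  between paired zones while the tunnel fans are off.

The **operating point** finds `ΔP ≥ 0` with fan demand
`fans_on·Q(ΔP)` equal to inlet + pad supply, by Brent's method on the
bracketed monotone residual (tolerances 1e-12 Pa absolute). The
returned flow set is the supply at that pressure, so mass balance is
exact by construction; the demand/supply residual left by the root
finder (≲10⁻⁹ of fan capacity) is reported. Degenerate input — fans
running against a fully sealed house — has no root and returns the
clamped boundary solution (cutoff pressure, zero flow) with a warning
flag.

## Six-zone transient model

The house (87 × 15 m footprint, 3.5 m eave, 5 m ridge → 63.75 m² gable
section, ≈5,546 m³) is split 2 × 3: zones 1–3 run along one side from
the end wall opposite the fans ("far") to the fan wall ("near"), zones
4–6 mirror them. Each zone is an ideally mixed tank of 924.4 m³;
through-flow follows the plug-flow chain far → mid → near on each
side, exhausting at the near-zone temperature. Per zone, the energy
balance is

```
ρ·cp·V·dT/dt = Σ ρ·cp·q·(T_upstream_or_inlet - T)   advection
             + Sh·V_bird                             flock heat
             + U·A_wall·(T_out - T)                  envelope (U = 0.247 W m⁻² K⁻¹)
             + ρ·cp·q_mix·(T_pair - T)               circulation mixing (fans off)
```

Baffle air enters its own zone at outdoor temperature (each inlet is
assigned to the nearest zone by side and section); pad air enters the
two far zones at the pad outlet temperature. The local air speed seen
by the birds is the zone through-flow over the 31.9 m² half
cross-section.

Integration is explicit Euler on the 1-s schedule step with automatic
sub-stepping whenever the advective stability bound
`ρcpV / (Σρcp·q + UA)` times a 0.5 safety factor is shorter than the
step; `min_substeps` forces refinement for step-halving studies
(halving changes a one-hour trajectory by < 0.01 °C here). Flock heat
is evaluated at the step's starting temperature and held across
substeps (temperature moves ≲0.05 K per second, so the lag is
negligible). Operating points are cached per distinct (fans_on,
opening vector) pair, which makes on-off replays cheap (a one-hour
replay runs in under a second). Non-finite temperatures abort with the
offending zone's flux terms in the message; energy terms are
accumulated exactly as applied, and the closure residual against the
change in internal energy is reported in the audit (machine precision
by construction; the test suite checks 0.1%).

Why the gradient points toward the fans: with uniform inlets the
stirred-tank chain alone gives an almost flat profile (each zone's
fresh-air share balances its heat share). The observed warm-near-fans
gradient emerges from the velocity dependence of `ra` — downstream
zones carry more through-flow, so their birds shed more heat — plus
the accumulation of upstream heat. Variable-inlet cases redistribute
the fresh air: more opening near the fans (case 1) short-circuits
fresh air to the exhaust and warms the house mean; more opening at the
far end (case 2) sweeps fresh air through the whole building and cools
it, at the cost of a steeper gradient.

## Schedules and scenarios

Controller logs are timestamped JSON events (`fans_on`, `baffles` as a
scalar, per-section or per-inlet mapping, `t_out`, `t_wb`); a change
applies from its own timestamp (inclusive-left, the common telemetry
convention) and is forward-filled to the 1-s grid. Schedules are
strictly gap-free; the CSV writer/reader round-trips exactly
(`float_precision="round_trip"`).

The synthetic generator emulates mild-weather thermostatic operation:
default one-hour horizon, 300-s period with 20% duty (60 s on / 240 s
off), 5 tunnel fans and 0.6 baffle opening while on, outdoor drift
14.8 → 12.7 °C. These defaults are the study conditions used
throughout the tests and the acceptance script. Optional seeded jitter
perturbs each cycle's on-length to mimic irregular thermostat runs.
What the generator does **not** emulate: varying fan counts within an
hour, partial-baffle modulation while off, weather fluctuations,
humidity, or infiltration — so passing tests demonstrate the model's
response to idealized cycling, not fidelity to any particular measured
hour.

Inlet sections split 10/9/10 (far/mid/near) per side. Equal far and
near section areas make the ±50% scenario swaps — case 1 = (0.5, 1.0,
1.5) multipliers, case 2 = (1.5, 1.0, 0.5) — conserve total open area
exactly for uniform inlets, which the transform verifies at every time
step (1e-9 relative) and which keeps the operating point, and hence
the total ventilation rate, identical across cases. Scaled fractions
must stay within [0, 1]: an opening cannot exceed fully open, so
baseline openings above 2/3 reject the 1.5× case rather than silently
clamping.

## Validation metrics

`signed_errors` (measured − simulated, with unit checking),
`agreement_percent` (100·simulated/measured), `rmse`, and
`gradient_metric` (mean of zones 3 and 6 minus mean of zones 1 and 4).
The packaged CSV tables carry the reference house's measured-vs-
simulated zone-centre velocities and inlet/pad airflow totals under 5-
and 14-fan operation; the metric functions reproduce their printed
summary statistics exactly, which anchors the arithmetic.

## Known limitations

* No humidity or latent balance of the house air; pads only cool the
  inflow stream.
* No infiltration (real houses leak, especially at the far-end door,
  which measurably cools the far zones).
* No surface-to-surface radiation, no litter thermal mass (floor
  temperature defaults to zone air temperature), uniform initial
  condition unless a per-zone vector is given.
* Zone-level resolution only: no in-zone velocity or temperature
  structure, and the inlet-jet trajectory (which in reality carries
  fresh air past its own zone) is approximated by nearest-zone
  assignment.
* Bird physiology constants are placeholder defaults; results scale
  with them and they should be calibrated per flock age/weight.
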