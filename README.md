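# lvrsim

A gravitational model of regional alveolar mechanics for simulating **lung
volume reduction in homogeneous emphysema** — for respiratory
physiologists and interventional-pulmonology researchers who want to
reason quantitatively about *where* in the lung volume reduction should be
performed.

## The model

The lung is a stack of alveolar layers from apex to base. Each alveolus
follows an exponential pressure–volume law

```
V(Ptp) = Vmax − A·e^(−k·Ptp),    A = Vmax − Vmin,
```

and transpulmonary pressure falls linearly with depth from the apex,
`Ptp(z) = Ptp(0) − ρ_frac·z`, with lung tissue at a fraction `ρ_frac`
(default 0.25) of water density. On deflation, airways close where
`Ptp(z)` drops to the closing pressure `Ptm′`, trapping gas at `V(Ptm′)`
in everything below. Whole-lung TLC, RV and the gas-trapping index RV/TLC
are obtained by integrating over all alveoli.

Severe homogeneous emphysema is represented by halving the alveolar count
(n = 150×10⁶), doubling the trapping ratio (Vmin/Vmax = 0.5), raising the
shape factor (k = 0.3 /cm H2O) and the closing pressure (Ptm′ = 1 cm H2O),
with apical recoil at full inflation of 12.5 cm H2O. The two degrees of
freedom the static physiology leaves open — the deflation-limb apical
pressure and the absolute volume scale — are calibrated once against the
baseline anchors RV/TLC = 0.68 and RV = 5.8 L (Brent root-finding and an
exact closed form, respectively).

Volume reduction therapy is then a parameter-free *prediction*: remove
alveoli from the upper or lower half of the lung, shorten it 35 → 33 cm,
raise Ptp across the volume range (recoil 12.5 → 14 cm H2O) and lower
Ptm′ to 0.5 cm H2O, keeping every constitutive parameter of the surviving
alveoli fixed. Because gravity concentrates gas trapping apically,
upper-lobe treatment removes the highest-RV/TLC alveoli and lowers the
population mean, while lower-lobe treatment removes low-RV/TLC alveoli
and is largely offset — the mechanism behind the clinical observation
that upper-lobe targeting works better in homogeneous disease.

See `docs/methods.md` for assumptions, numerics and limitations.

## Worked example

```python
import lvrsim as lv

base = lv.emphysema_preset()   # calibrates both free parameters
print(f"calibrated deflation pressure: {base.p_rv_apex:.3f} cm H2O")
result = lv.compare_ult_llt(base, lv.ult_treatment(base), lv.llt_treatment(base))
s = result.baseline
print(f"baseline:  TLC {s.tlc:.2f} L  RV {s.rv:.2f} L  RV/TLC {s.rv_tlc:.3f}")
for arm, summary in (("ULT", result.post_ult), ("LLT", result.post_llt)):
    d = result.delta_rv_tlc_percent[arm.lower()]
    print(f"post-{arm}:  TLC {summary.tlc:.2f} L  RV {summary.rv:.2f} L  "
          f"RV/TLC {summary.rv_tlc:.3f}  ({d:+.1f}%)")
```

prints

```
calibrated deflation pressure: 2.436 cm H2O
baseline:  TLC 8.53 L  RV 5.80 L  RV/TLC 0.680
post-ULT:  TLC 7.44 L  RV 4.83 L  RV/TLC 0.649  (-4.6%)
post-LLT:  TLC 7.49 L  RV 5.01 L  RV/TLC 0.669  (-1.7%)
```

The baseline reproduces its calibration anchors (0.680, 5.80 L). The
treatment rows are emergent: upper-lobe volume reduction lowers whole-lung
RV/TLC by almost three times as much as the identical lower-lobe
procedure, even though both remove 22 million alveoli under the same
pressure and height shifts. A sensitivity scan
(`lvrsim.dominance_scan`) shows ULT is at least as effective as LLT at
every point of a ±25% grid over (n, k, Vmin/Vmax, Ptm′).

## Command line

Each command takes a YAML config validated against
`docs/config.schema.json` (see `examples/`):

```sh
lvrsim simulate --config examples/healthy.yaml            --out out/   # regional_profile.csv, summary.json
lvrsim calibrate --config examples/emphysema_treatment.yaml --out out/ # calibration.json with provenance
lvrsim treat     --config examples/emphysema_treatment.yaml --out out/ # comparison.json (ULT vs LLT)
lvrsim sweep     --config examples/emphysema_treatment.yaml --out out/ # sweep.csv, dominance.json
```

Outputs are deterministic and byte-identical across repeated runs;
per-layer CSVs carry both depth-from-apex and distance-from-base axes.

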