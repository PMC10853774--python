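# minishape

Design and SHAPE-based evaluation of minimized ribosomal RNA constructs.

The peptidyl transferase center (PTC) — the catalytic core of the large
ribosomal subunit — is built in *E. coli* from three noncontiguous segments of
23S rRNA domain V. A minimized, protein-free PTC RNA can be made by excising
those segments (residues 2043–2091, 2228–2258 and 2426–2625), capping the
truncated helix H75 with a stable A4 tetraloop, and joining the remaining loops
directly, giving a 284-nt single strand; adding 5′/3′ reference hairpins with
GAGUA loops gives the 357-nt construct used for quantitative SHAPE probing.
`minishape` implements the computational workflow around such constructs:

- **construct assembly** from native-numbered segments and synthetic junctions,
  with a bijective construct ↔ native coordinate map (`construct`);
- **mutation tools**: parse `C2043U`-style notation, apply/diff mutation sets,
  and validate designs against allowed-position and budget constraints
  (`mutations`);
- **SHAPE reactivity processing**: background subtraction of replicate
  modification/control measurements, GAGUA reference-hairpin normalization,
  unit scaling and heatmap classification (`reactivity`);
- **profile comparison**: Pearson (optionally noise-disattenuated) correlation
  between experimental and predicted profiles, differential profiles
  Δᵢ = expᵢ − predᵢ, maximum-likelihood distribution selection
  (Cauchy/Normal/Laplace/Logistic ranked by histogram SSE), extreme-outlier
  calling with Tukey fences at Q1 − 3·IQR / Q3 + 3·IQR, region assignment and
  design ranking (`compare`);
- **footprinting and yields**: ligand-protection calls from free/bound profile
  pairs, overlap with a reference protected-residue set, extracted-ion
  chromatogram (±ppm) integration and the fragment-reaction yield
  `(area_product / area_standard) × 10³` (`footprint`);
- **synthetic data**: seeded generators for every input the pipeline consumes,
  with recorded ground truth for parameter-recovery tests (`simulate`).

## Worked example

```python
import minishape as ms

core = ms.wt_mini_ptc(seed=0)  # 284-nt minimized PTC from a synthetic source
print(f"core construct: {len(core)} nt")
print(f"native 2426 -> construct index {core.native_to_construct(2426)}")
print(f"P-loop motif: {ms.motif_lookup(core, ms.DEFAULT_REGIONS[0])}")

catalog = ms.design_catalog()
mutant = ms.apply_mutations(core, catalog["mini-PTC 1.1"])
diff = ms.diff_sequences(core, mutant)
print(f"mini-PTC 1.1 differs from WT at {len(diff)} positions")

exp, pred, _ = ms.simulate_profile_pair(284, target_rho=0.61, seed=7)
res = ms.pearson_correlation(exp, pred)
print(f"predicted-vs-experimental rho = {res.rho:.2f} "
      f"over {res.n_positions} positions")

deltas = ms.differential_profile(exp, pred,
                                 labels=[e.label for e in core.coords])
planted, _ = ms.plant_outliers(
    deltas, [(core.native_to_construct(2453), 0.9, "high")])
report = ms.assign_regions(ms.iqr_outliers(planted), ms.DEFAULT_REGIONS)
print(f"fences [{report.lower_fence:.2f}, {report.upper_fence:.2f}]; "
      f"{len(report.outliers)} extreme outlier(s)")
for o in report.outliers:
    print(f"  native {o.position}: delta {o.delta:+.2f} ({o.sign}, {o.region})")
```

Output:

```text
core construct: 284 nt
native 2426 -> construct index 85
P-loop motif: UGGGGCG
mini-PTC 1.1 differs from WT at 12 positions
predicted-vs-experimental rho = 0.60 over 284 positions
fences [-0.63, 0.72]; 1 extreme outlier(s)
  native 2453: delta +0.90 (high, central loop)
```

The 284-nt core is the concatenation of the three domain-V spans (49 + 31 +
200 nt) plus the 4-nt tetraloop; native residue 2426 lands at construct index
85 because 49 segment residues, 4 tetraloop residues and 31 more segment
residues precede it. The design `mini-PTC 1.1` carries 12 substitutions
relative to the unmutated construct, recovered exactly by `diff_sequences`.
The differential-reactivity outlier at native 2453 — planted 0.9 units above
the predicted reactivity — exceeds the upper Tukey fence (Q3 + 3·IQR = 0.72)
and is assigned to the central loop.

A `minishape` console script exposes the same stages
(`assemble`, `mutate`, `diff`, `validate`, `normalize`, `compare`, `rank`,
`footprint`, `yield`, `simulate`); see `minishape --help`.

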