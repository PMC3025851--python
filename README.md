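# corspec

Analysis tools for the ligand specificity of vertebrate corticosteroid
receptors — mineralocorticoid receptors (MR) and the duplicate
glucocorticoid receptors (GR1, GR2) of teleost fishes — as measured by
GAL4–LBD luciferase transactivation assays.

Receptor ligand-binding domains (LBDs) fused to a heterologous DNA-binding
domain drive a luciferase reporter in response to steroid treatment. From
such assays the package answers four questions:

1. **Which steroids activate which receptor?** Raw luminescence is
   normalized to the vehicle (ethanol) signal of the same construct, and a
   one-sample, one-sided t-test per receptor × ligand pair at a single
   screen dose (10⁻⁷ M by default) yields a `+` / `0` / `NA` sensitivity
   matrix.
2. **How sensitive?** Dose-response series over a ten-fold ladder
   (10⁻¹¹–10⁻⁶ M) are fitted with a fixed-baseline three-parameter logistic

   f(x) = β₁ + (1 − β₁) / (1 + (x/β₂)^β₃)

   where β₁ is the upper bound in fold-activation units, β₂ the EC50
   (molar) and β₃ the shape; the zero-dose response is pinned at the
   vehicle baseline of 1. A four-parameter variant with a free zero-dose
   asymptote β₀ is available for constructs with constitutive low-dose
   activity. Because activity often *declines* at the top of the ladder
   (cytotoxicity), doses above the dose of maximum mean response (d_M) are
   excluded before fitting; the fit is run from a grid of 27 starts with
   bounded least squares on log₁₀(dose) and the smallest-RSS fit is kept.
3. **Which residues explain specificity differences?** Given a protein
   alignment and a two-group sensitivity assignment, the scan reports every
   column conserved within each group but different between groups (and
   gap-free) — candidate specificity-determining positions — and maps LBD
   coordinates to full-length receptor numbering (LBD position 1 = residue
   538 of mouse GR, 532 of human GR).
4. **Does sensitivity track the phylogeny?** A binary
   sensitive/insensitive character is placed on a user-supplied receptor
   tree and the minimum number of state changes is computed by unit-cost
   small parsimony; more than one change means the trait pattern cannot be
   explained by a single origin.

Because raw assay measurements of this kind are rarely deposited, the
package ships a first-class synthetic-data generator (logistic dose
dependence, multiplicative noise, optional high-dose cytotoxic decline;
alignments with planted discriminating columns) so that every stage can be
validated against known truth.

## Worked example

```python
import corspec as cs

# simulate a mouse-MR-like aldosterone series: EC50 0.2 nM, 8-fold maximum
cfg = cs.DoseResponseSimConfig(
    construct="mouse_MR", ligand="aldosterone",
    beta1=8.0, beta2=2e-10, beta3=1.0, noise_cv=0.1, seed=1,
)
raw = cs.simulate_dose_response(cfg)

(series,) = cs.normalize_to_vehicle(raw)
trimmed, d_max, excluded = cs.truncate_at_max_mean(series)
fit = cs.fit_dose_response(trimmed, excluded_doses=excluded, d_max=d_max)
print(f"EC50 = {cs.estimate_ec50(fit, unit='nM'):.3f} nM "
      f"(beta1 = {fit.params.beta1:.2f}, rss = {fit.rss:.3f})")
```

prints

```
EC50 = 0.179 nM (beta1 = 7.48, rss = 0.860)
```

i.e. from one noisy simulated series the pipeline recovers the planted
0.2 nM EC50 to within sampling error, with the fitted maximum activation
(7.48-fold) close to the planted 8-fold.

The same stages are available from the shell:

```sh
corspec simulate --config sim.yaml --out data/ --seed 7
corspec fit data/measurements.csv --out ec50_table.csv
corspec screen data/measurements.csv --out sensitivity.csv
corspec sdp data/alignment.fasta data/groups.csv --out sites.csv
corspec lability tree.nwk states.csv --out report.json
```

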