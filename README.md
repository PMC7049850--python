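# tumor-immune

Simulation and analysis of a tumor–immune interaction model with CD4⁺ T-cell
therapy.

The package is for modellers studying how a growing tumor interacts with the
innate and adaptive immune system, and what continuous or pulsed regimens of
chemotherapy and immunotherapy (IL-2, adoptive CD8⁺ or CD4⁺ T cells) can
achieve. It implements, for two reference patient parameterizations:

* the six-population model and its seven-state treated extension,
* a fixed-step Adams–Bashforth/Moulton predictor–corrector integrator
  (orders 1–12) with exact-rational coefficient generation,
* closed-form and root-found equilibria with linear stability analysis,
* one-parameter bifurcation sweeps with bisection-refined critical values,
* a registry of named treatment scenarios with eradication verdicts.

## The model

State variables: tumor cells `T`, natural killer cells `N`, CD8⁺ T cells `L`,
CD4⁺ T cells `Y`, circulating lymphocytes `C`, IL-2 concentration `I`, and —
under chemotherapy — drug concentration `M`.

```
dT/dt = a T (1 − b T) − c N T − D T − c₁ T/(a₁+T) · I − K_T (1 − e^(−M)) T
dN/dt = e C − f N + g T²/(h+T²) · N − p N T − K_N (1 − e^(−M)) N
dL/dt = −m L + j D²T²/(k+D²T²) · L − q L T + (r₁ N + r₂ C) T
        − u N L² + p_I I/(g_I+I) · L − K_L (1 − e^(−M)) L + v_L(t)
dY/dt = β₁ T/(α₁+T) · I − μ₁ Y − δ₂ T Y + v_Y(t)
dC/dt = α − β C − K_C (1 − e^(−M)) C
dI/dt = −μ_I I + β₂ T/(α₂+T) · Y + v_I(t)
dM/dt = −γ M + v_M(t)
```

with the saturating CD8⁺ lysis fraction `D = d (L/T)^l / (s + (L/T)^l)`,
evaluated internally as `d L^l / (s T^l + L^l)` so that the product `D·T`
stays defined as `T → 0`. Tumor kill by CD4⁺ T cells is indirect: `Y` drives
the cytokine `I`, and `I` kills through the `c₁ T/(a₁+T)·I` term.

Key closed forms:

* tumor-free equilibrium `(0, eα/(fβ), 0, 0, α/β, 0)`;
* recurrence condition: the tumor-free state is stable iff
  `a − c e α/(f β) < 0`, giving critical values `a* = c e α/(f β)` and
  `c* = a f β/(e α)`;
* active-cytokine equilibria: tumor sizes are positive roots of a cubic in
  `T` built from the CD4/cytokine constants only.

Two parameter sets ("patient1", "patient2") ship as YAML fixtures under
`src/tumor_immune/data/`.

## Worked example

Enumerate and classify the second patient's equilibria:

```python
>>> import tumor_immune as ti
>>> df = ti.equilibria_table(ti.patient2())
>>> print(df[["branch", "T", "N", "L", "Y", "I", "verdict"]].to_string(index=False))
                        branch            T             N             L            Y            I  verdict
                    zero_tumor 0.000000e+00 315533.980583      0.000000 0.000000e+00 0.000000e+00 unstable
   nonzero_tumor_zero_cytokine 1.274226e+06   2824.139510 450072.972357 0.000000e+00 0.000000e+00 unstable
nonzero_tumor_nonzero_cytokine 3.506429e+06   1030.373751 952786.779646 4.553932e+06 2.458422e+06 unstable
```

Three steady states: tumor-free (N ≈ 3.16e5 NK cells sustained by the
lymphocyte pool), a 1.27-million-cell tumor held by NK/CD8⁺ pressure alone,
and a 3.51-million-cell tumor with the CD4⁺/IL-2 loop active. All three are
unstable — eradication is not self-maintaining, and an untreated tumor can
escape — which is why the treatment scenarios matter.

Run a treatment scenario from the shell:

```
$ tumor-immune scenario run p2_triple_continuous
{
  "name": "p2_triple_continuous",
  "eradicated": true,
  "eradication_day": 8.986328125,
  "min_tumor": 2.885430881174079e-37,
  ...
}
```

Combined CD8⁺ + IL-2 + CD4⁺ infusion clears the million-cell tumor in about
nine days; either arm alone fails (`tumor-immune scenario matrix` prints all
verdicts). Other entry points: `tumor-immune simulate` (custom initial state
and schedule → trajectory CSV), `tumor-immune equilibria`,
`tumor-immune bifurcate`.

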