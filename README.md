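# pseudoneglect

Reliability analysis of spatial bisection tasks.

Healthy adults asked to find the midpoint of a line tend to err slightly
to the left — *pseudoneglect*, the neurotypical mirror image of the
rightward bias seen in spatial neglect. Whether that bias is a stable
trait of a person, and whether it is the *same* trait across sensory
modalities, is a test–retest reliability question. This package provides
the full analysis chain for multi-session bisection studies spanning
three task families:

* **landmark** — a 2AFC judgement of which side of a pre-bisected line is
  longer (purely perceptual);
* **line bisection** — manual transection of a visual line with a stylus
  (visuomotor);
* **rod bisection** — tactile transection of a physical rod while
  blindfolded (haptic).

It is aimed at researchers running or simulating such studies: it
enumerates counterbalanced trial lists, simulates observers with known
latent biases, fits psychometric functions, builds bisection-error
matrices, quantifies reliability, runs the group inference, and sizes
future studies by Monte-Carlo power analysis.

## The models and statistics

**Psychometric model (landmark).** The probability of a "right side
longer" response at signed stimulus asymmetry $x$ (mm, rightward
positive) is

$$p(x) = \lambda + (1 - 2\lambda)\,\Phi\!\left(\frac{x - \alpha}{\sigma}\right),$$

with threshold $\alpha$, slope SD $\sigma$, and lapse rate $\lambda$,
the guess rate fixed equal to $\lambda$. All three parameters are
estimated jointly by maximising the binomial likelihood over every
stimulus level, from a deterministic multistart grid; uncertainty comes
from a non-parametric bootstrap of the per-level counts. The point of
subjective equality (PSE) is the 50% crossing, which under the symmetric
lapse constraint equals $\alpha$; landmark bisection error is $-\mathrm{PSE}$
so that leftward biases are negative, commensurate with the manual tasks
(error = perceived midpoint − physical midpoint, in mm).

**Reliability.** Cronbach's $\alpha$ — the average-measures consistency
ICC, ICC(3,k) — over the participants × sessions (or participants ×
tasks) error matrix:

$$\alpha = \frac{k}{k-1}\left(1 - \frac{\sum_i s_i^2}{s_\text{total}^2}\right)
         = \frac{MS_\text{rows} - MS_\text{err}}{MS_\text{rows}},$$

with significance from the two-way-ANOVA F test
$MS_\text{rows}/MS_\text{err}$ on $(n-1, (n-1)(k-1))$ df. The
absolute-agreement ICC(2,k) is computed alongside for contrast.

**Group inference.** One-sample t-tests (with Cohen's $d = \bar{x}/s$)
per session and per task under Bonferroni-adjusted levels
($0.05/4 \to 0.013$, $0.05/3 \to 0.017$), and the 3 (task) × 4 (session)
fully-within-subjects ANOVA with effect-specific error strata and partial
$\eta^2$.

**Power.** Monte-Carlo power for (i) the $\alpha$-significance F test,
drawing matrices from the variance-component model whose population
consistency equals the hypothesised $\alpha$
($\alpha = \sigma_b^2/(\sigma_b^2 + \sigma_e^2/k)$), and (ii) the
one-sample t-test, cross-checked against the noncentral-t closed form.

## Worked example

Simulate a 24-participant, 4-session study with the default population
(calibrated to published healthy-adult effect sizes) and run the whole
pipeline:

```python
from pseudoneglect.report import PipelineConfig, run_pipeline

rep = run_pipeline(PipelineConfig(seed=1))
print(rep.reliability_by_task[["alpha", "f_stat", "p_value"]].round(3))
```

```
                alpha  f_stat  p_value
task
landmark        0.534   2.144    0.008
line_bisection -0.249   0.801    0.719
rod_bisection   0.635   2.741    0.001
```

Cross-session consistency is significant for the landmark and rod tasks
but absent for line bisection — with population values of about 0.8,
0.63 and ≈0 respectively, and substantial sampling spread at n = 24.
Across tasks the biases dissociate:

```python
print(rep.cross_task_reliability[["alpha", "p_value"]].round(3))
#    alpha  p_value
# 0 -0.446    0.829
```

and the group shows an overall leftward bias:

```python
print(rep.ttests.tail(1)[["mean", "sd", "t", "p_value", "cohens_d"]].round(3))
#     mean     sd      t  p_value  cohens_d
# 7 -1.341  1.206 -5.445      0.0    -1.111
```

i.e. a grand-mean bisection error of −1.34 mm (leftward), t(23) = −5.45.
Each number in the report is traceable to a module output
(`session_matrices`, `task_matrix`, `anova`, `screening`, ...), and
`PipelineConfig(output_dir=...)` writes every table as delimited text
plus a manifest with the seed and config digest.

The same stages are exposed as a CLI:

```sh
pseudoneglect simulate --seed 1 --out study/
pseudoneglect fit study/trials.tsv --participant P01 --session 1
pseudoneglect power --test cronbach --effect 0.8 --n 30 --k 4
pseudoneglect report --seed 1 --out results/
```

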