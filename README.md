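# seqswap

Simulation and analysis of **context-cued serial-order learning with
object re-indexing** — the behavioral paradigm in which rhesus macaques
learn to touch five objects in a fixed order (A-B-C-D-E) and, cued only by
a change of background context, must re-order the *non-adjacent* objects B
and D into the new sequence A-D-C-B-E.

The scientific question the analyses address is how a subject represents
serial order. At the second ordinal position of the re-ordered sequence,
two representations make different predictions immediately after a correct
choice of A:

* **position coding / re-indexing** — objects are bound to absolute
  positions of an abstract sequence; the context cue re-binds B and D, so
  the subject pro-actively chooses **D**;
* **serial chaining / serial inference** — the sequence is a chain of
  item-item links; displacing B points to the next-in-chain object, so the
  subject erroneously chooses **C**.

The package is aimed at behavioral researchers who want to run, stress or
extend this analysis pipeline without access to animal data: a generative
task simulator stands in for the subjects.

## What's inside

| module | contents |
| --- | --- |
| `seqswap.types` / `seqswap.io` | domain types with full task-invariant validation; canonical tab-delimited choice log (one row per touch, DMTS trials co-stored) |
| `seqswap.simulate` | value-learning agent with a position/serial/exploration strategy mixture at the context switch, DMTS generator coupled to a latent working-memory ability, session skeleton with repeats and background effects |
| `seqswap.learning` | completion curves, 80%-sustained learning criterion, 4-parameter logistic fits, ordinal-position accuracy with forward-looking chance 1/(7−p), four-type error taxonomy with exponential-decay fits, RT summaries, proficiency terciles |
| `seqswap.swap` | transition tables after conditioning events, pro-/retro-active swap indices, first-choice analyses, Welch t, Bonferroni/BH-FDR, two-proportion Z, OLS with Cohen's f² |
| `seqswap.bayes` | multinomial choice-probability model with Beta(2,5) priors on raw components, component-wise Metropolis-Hastings (step 0.05, 200k iterations, 100k burn-in, 4 chains), Gelman-Rubin R̂, running means, posterior ordering probabilities, strategy classification |
| `seqswap.sessions` | new-early/repeat/new-late comparisons, proficiency and across-session regressions, DMTS-swap correlation (OLS + mixed model), same/different-background context effects, consolidated JSON/markdown report |

The core statistical model: second-position choice counts
y = (y_B, y_C, y_D, y_E, y_X) are multinomial with probability vector θ,
P(y | θ) ∝ ∏ₖ (θₖ/Σθ)^yₖ, with independent Beta(α=2, β=5) priors on each
raw component; posterior draws are normalized and the strategy call is the
argmax of the posterior ordering masses P(θ_D > θ_B ∧ θ_D > θ_C)
(position coding) versus P(θ_C > θ_B ∧ θ_C > θ_D) (serial inference).

## Worked example

```python
import numpy as np
from seqswap import (AgentParams, GeneratorConfig, MCMCConfig,
                     classify_strategy, completion_curve, mh_sample,
                     simulate_sessions, swap_indices, transition_after,
                     trials_to_criterion)

agent = AgentParams(seed=7)                  # default, position-leaning agent
sessions = simulate_sessions(agent, GeneratorConfig(n_sessions=12))
blocks = [b for s in sessions for b in s.blocks]

for ctx in (1, 2):
    curve = completion_curve(blocks, ctx)
    crit = trials_to_criterion(curve)
    print(f"context {ctx}: criterion trial {crit.criterion_trial}, "
          f"final completion {curve.proportions[-1]:.2f}")

idx = swap_indices(blocks)
print(f"pro-active index  {idx.proactive:+.3f}  ({idx.n_proactive_events} events)")
print(f"retro-active index {idx.retroactive:+.3f}  ({idx.n_retroactive_events} events)")

table = transition_after(blocks, "after_correct_A")
counts = np.array([table.counts[table.labels.index(l)]
                   for l in ("B", "C", "D", "E", "X")])
print("second-position counts (B,C,D,E,X):", counts.astype(int).tolist())
post = mh_sample(counts, MCMCConfig(seed=7))
for lab in ("B", "C", "D"):
    print(f"posterior mean theta_{lab} = {post.mean(lab):.3f}")
print(f"max R-hat = {post.rhat.max():.4f}")
call = classify_strategy(post)
print("strategy:", call.label,
      {k: round(v, 3) for k, v in call.region_probabilities.items()})
```

prints

```
context 1: criterion trial 5, final completion 1.00
context 2: criterion trial 1, final completion 1.00
pro-active index  +0.325  (126 events)
retro-active index +0.188  (16 events)
second-position counts (B,C,D,E,X): [6, 57, 47, 7, 9]
posterior mean theta_B = 0.061
posterior mean theta_C = 0.427
posterior mean theta_D = 0.360
max R-hat = 1.0002
strategy: serial_inference {'position_coding': 0.178, 'serial_inference': 0.822, 'other': 0.0}
```

Reading the output: the agent needs five trials to master a new sequence
in context 1 but is immediately at criterion after the context switch —
the signature of re-indexing rather than relearning. The pro-active index
(+0.33) says D is chosen far more often than B right after a correct A,
and the retro-active index (+0.19) says an error on B is corrected toward
D more often than toward C. The pooled *pre-criterion* posterior
nevertheless leans serial (θ_C slightly above θ_D): trials on which the
agent re-indexes complete immediately and leave the pre-criterion window,
so that window over-represents serial and exploratory stretches — a
selection effect discussed in `docs/methods.md`, and the reason per-block
regressions use a fixed early-trial window instead. All four chains agree
(R̂ ≈ 1.0002).

The same pipeline is scriptable from the shell:

```bash
seqswap simulate --seed 7 --sessions 2 --out run/
seqswap analyze  --log run/choices.tsv --seed 7 --out run/analysis/
seqswap bayes    --log run/choices.tsv --chains 4 --seed 7 --out run/bayes/
seqswap report   --indir run/analysis --out run/report/
```

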