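# blockhmm

Block-level hidden Markov modeling of choice-transition strategies in
two-alternative reversal learning.

## The problem

In a reversal-learning task the high-reward side flips at unsignaled block
boundaries, and a subject's within-block recovery is summarized by a
sigmoidal *choice-transition function*

σ(t) = ε + (1 − 2ε) / (1 + exp(−α (t − s)))

with switch offset *s* (trials), slope *α* (1/trials) and lapse *ε*.
Subjects — mice in particular — rarely execute one such transition strategy
uniformly: block-to-block performance is far more variable than any single
curve predicts.  This package models a session as a **hidden Markov chain
over blocks**: each hidden mode carries its own (s, α, ε), the emission
likelihood of a whole block is the joint Bernoulli likelihood of its signed
choices under that mode's sigmoid, and modes persist and switch block-to-
block via a K × K transition matrix.  Fitting is by EM with exact
forward–backward; the number of modes is chosen by normalized
cross-validated log-likelihood, L_norm = (L_test − L_0)/(n_test log 2).

Around the model the package provides, for behavioral scientists analyzing
reversal-learning data:

* simulators for the two standard algorithmic agent families — model-free
  Q-learning (q ← q + γ(r − q), ε-greedy) and an inference-based Bayesian
  observer (internal Markov world model with P_switch, P_rew) — plus the
  alternating-block task environment;
* a regime-mapping pipeline that clusters 650 simulated agents into six
  regimes (Q1–Q4, IB5–IB6) from their transition features (ε, α, s, and
  foraging efficiency E = normalized area under σ on trials 1–25) and trains
  a class-balanced kNN decoder that labels fitted modes with the algorithm
  family that best accounts for them;
* behavioral benchmarks: session metrics, the win-stay-lose-shift ideal
  agent, per-block maximum-likelihood sigmoid fits, a bootstrap test for
  non-uniform strategies, and an early-switch refit that exposes negative
  offsets (anticipatory switching);
* seeded synthetic-data generators and a session CSV format, so the whole
  pipeline is testable without any experimental data.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

Sample behavior from a three-mode agent (a high-lapse drifter, a fast
switcher and a sharp-but-delayed switcher with sticky mode dynamics), pick
the number of modes by cross-validation, fit, and classify the modes:

```python
import numpy as np
from blockhmm import (BlockHMM, classify_mode, foraging_efficiency,
                      make_reference_agent, select_num_modes)

agent = make_reference_agent()            # K=3, modes (4,0.2,0.3), (1,0.8,0.15), (9,1.5,0.05)
states, Y = agent.sample(1000, 30, random_state=1)

K = select_num_modes(Y, range(1, 7), random_state=1)
print("selected K =", K)

fit = BlockHMM(n_modes=K, n_restarts=5, random_state=0).fit(Y)
for m in fit.modes_:
    E = foraging_efficiency(m)
    print(f"s={m.offset:5.2f}  alpha={m.slope:4.2f}  eps={m.lapse:4.2f}"
          f"  E={E:4.2f}  {classify_mode(m, E).value}")

# fitted mode order is arbitrary: match each fitted mode to the nearest
# generating mode by offset before scoring the state decoding
match = np.array([np.argmin(np.abs(agent.offsets_ - s)) for s in fit.offsets_])
print("block-state decoding accuracy:",
      round(float(np.mean(match[fit.states_] == states)), 3))
```

prints

```
selected K = 3
s= 3.59  alpha=0.19  eps=0.30  E=0.61  low
s= 8.94  alpha=1.35  eps=0.05  E=0.65  intermediate_high_offset
s= 1.10  alpha=0.85  eps=0.16  E=0.82  intermediate_high_lapse
block-state decoding accuracy: 0.998
```

The three generating modes are recovered (offsets 4/1/9, slopes
0.2/0.8/1.5, lapses 0.3/0.15/0.05) and 99.8% of blocks are assigned their
true generating mode.  The per-mode efficiencies classify the modes into
the low / intermediate / high performance taxonomy: the flat high-lapse
mode forages at 61% (low), the sharp but delayed switcher at 65%
(intermediate, high offset), and the fast switcher at 82% (intermediate,
high lapse).

A command-line interface mirrors the main entry points:

```bash
blockhmm simulate --agent ib --pswitch 0.3 --prew 0.95 --blocks 200 --seed 1 --out session.csv
blockhmm metrics --input session.csv
blockhmm select-k --input session.csv --kmax 4
blockhmm fit --input session.csv --K 1 --out model.json
blockhmm variability-test --input session.csv
```

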