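# grnexplore

Curiosity-driven exploration and robustness profiling of gene-network ODE
models.

Biological pathway models — gene regulatory, protein signaling, metabolic —
can typically reach many more steady states than a naive screen of initial
conditions reveals, because the mapping from interventions to outcomes is
highly nonlinear and redundant. `grnexplore` treats such a network as an
agent navigating a low-dimensional *behavior space* Z (for example, the
endpoint concentrations of two phenotype nodes) and provides automated
tools to

1. **map the reachable goal states** with an intrinsically-motivated goal
   exploration process (IMGEP, "curiosity search") that is far more
   sample-efficient than uniform screening,
2. **stress-test each discovered goal** under trajectory-conditioned
   perturbations (gene-expression noise kicks, sudden pushes in
   transcriptional space, hard wall barriers),
3. **reuse the resulting behavioral catalog** for pseudopotential energy
   landscapes (U = −ln P), stepwise-clamp intervention design, and
   diversity-driven oscillator-circuit engineering.

## The core algorithm

Given a system (model, intervention space I, behavior space Z), the IMGEP
bootstraps with N_init rollouts from i ~ U(I), then iterates:

1. sample a goal g uniformly in the bounding box of already-reached goals
   {z_k}, scaled by 1.3 about its center;
2. find the reached goal nearest to g and its intervention i*;
3. mutate: i = clip(i* + ε), ε ~ N(0, 0.1·(I_high − I_low)) per dimension;
4. roll out, encode z = R(o), append (i, o, z) to the catalog H.

Because goals are drawn uniformly in *behavior* space, redundant regions of
I (many interventions, one outcome) stop absorbing the budget.

Discovered diversity is scored by **threshold coverage** — the area of the
union of ε-balls (ε = 0.05) around the reached points after rescaling Z to
the unit square, denominated by the (1+2ε)²-padded square. A system with
four isolated attractors can never exceed 4πε²/(1+2ε)² ≈ 0.026.

**Sensitivity** of a goal z is the mean over a battery of P = 18×3
perturbations of ‖z_p − z‖₂ normalized by the extent of the unperturbed
trajectory in Z; low sensitivity marks a *robust* goal.

Two model classes are built in: the transcriptional gene circuit
y(t+Δt) = (Δt/τ)·σ(Wy + B) + (1 − Δt/τ)·y (compiled, with exact
reverse-mode gradients for Adam-based circuit optimization), and a generic
`rate_fn(y, t)` ODE contract integrated at tolerances atol 1e−6 /
rtol 1e−12 on a uniform output grid (T = 2500 s, Δt = 0.1 s → 25,001
points). An SBML model can be wrapped by supplying its rate function as an
`OdeModel`.

## Worked example

Explore a 2-node circuit and measure the discovered diversity:

```
$ python - <<'EOF'
import numpy as np
from grnexplore.dynamics import GeneCircuitModel
GeneCircuitModel(np.array([[1.0,-2.0],[0.5,1.0]]),
                 np.array([0.2,-0.3]), np.ones(2)).to_json('model.json')
EOF
$ grnexplore explore --model model.json --budget 100 --seed 1 --horizon 200 --out cat_demo
[grnexplore 0.1.0] explore config-hash=d7c058c1ce83 seed=1
wrote catalog with 100 records to cat_demo
$ grnexplore metrics --catalog cat_demo --epsilon 0.05
threshold coverage (epsilon=0.05): 0.006
```

The coverage 0.006 means the 100 reached endpoints fill 0.6% of the
(padded, normalized) behavior square — this mild 2-node circuit funnels
most initial states to one attractor. The oscillator benchmark compares
search strategies on the 3-node circuit-design task:

```
$ grnexplore bench-oscillator --budget 200 --seed 7 --method random --horizon 500
target: A=0.350 omega=0.1712 b=0.619
 random: oscillators=1 best_loss=332.3 coverage=0.0001 finetuned=323.4
```

i.e. uniform sampling of 200 (y0, W, B) parameterizations found one
sustained oscillator; its best rollout sits at squared-error 332 from the
target cosine, improved to 323 by a 100-step Adam finetune. Use
`--method all` to compare Adam, CMA-ES, random and curiosity search at an
equal budget.

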