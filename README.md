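# pocketforge

Interaction-conditioned 3D ligand design inside protein binding pockets.

Structure-based generative models tend to memorize the complexes they were
trained on: given an unseen target, they produce familiar scaffolds making
unfavorable contacts. pocketforge implements a two-stage framework that
instead leans on the *universal* chemistry of protein–ligand recognition —
hydrogen bonds, salt bridges, hydrophobic contacts, and π–π stacking — as
an explicit, controllable prior:

1. **Interaction profiling.** Every pocket atom is labeled with one of
   seven classes — anion, cation, H-bond donor, H-bond acceptor, aromatic,
   hydrophobic, non-interacting — either from rules on the bare pocket
   (*reference-free*), by geometric profiling of a bound complex
   (*reference-based*), or by hand (*manual*, e.g. to target mutated
   residues). The per-atom one-hot matrix **I** is the condition.
2. **Conditional autoregressive generation.** A conditional VAE factorizes
   the ligand distribution atom by atom,

   p(**L** | **P**, **I**) = ∏ₜ p(**X**ₜ | C₍ₜ₋₁₎, **I**) ·
   p(**r**ₜ | **X**ₜ, C₍ₜ₋₁₎, **I**) · p(stop | **L**, **P**, **I**),

   where C₍ₜ₋₁₎ is the partial complex. Each step combines per-anchor
   type log-likelihoods from the placed ligand atoms and, weighted by a
   distance-dependent pocket coefficient λ, from the k nearest pocket
   atoms of the current atom-of-interest; positions are decoded as
   distance distributions on a Gaussian-expanded grid and realized on a
   spherical candidate shell around the anchor. All learned functions see
   interatomic distances only, so every prediction is E(3)-invariant by
   construction. The network runs on a small, self-contained numpy
   autodiff (`pocketforge.nn`).

Evaluation utilities cover interaction fingerprints (4 bits per pocket
atom) and their cosine similarity, Bemis–Murcko scaffold diversity and
novelty, per-type interaction counts and distance distributions, and a
selectivity screen at the 2.72 kcal/mol (100-fold potency) criterion.

A synthetic-fixture module builds small pocket+ligand complexes with
designed interaction motifs at exact geometries, so the entire pipeline —
I/O, profiling, training, generation, evaluation — runs and is tested
with no external data.

## Worked example

Train on a twin-site pocket — two chemically identical carbonyl acceptor
sites on opposite sides, with two reference complexes whose conditions
mark opposite sites — then compare generation under the reference
condition against the masked (all-zero) condition:

```python
import numpy as np
from pocketforge import ModelConfig, TrainConfig, SamplerConfig, fit, generate
from pocketforge.fixtures import make_conditioning_pair
from pocketforge.profiler import (
    detect_interactions, interaction_fingerprint, interaction_similarity,
    mask_condition,
)

pair = make_conditioning_pair(seed=0)
dataset = [(pocket, ligand, cond) for pocket, ligand, cond, _ in pair]
result = fit(dataset, ModelConfig.toy(),
             TrainConfig(epochs=400, seed=1, learning_rate=5e-3,
                         final_learning_rate=1e-4))
print(f"final reconstruction loss: {result.history[-1]['recon']:.2f} "
      f"(epoch 1: {result.history[0]['recon']:.2f})")

pocket, _, condition, interactions = pair[0]
reference_fp = interaction_fingerprint(pocket, interactions)
sampler = SamplerConfig(n_directions=64, max_atoms=4)

def mean_similarity(cond, seed):
    rng = np.random.default_rng(seed)
    sims = []
    for _ in range(50):
        mol = generate(pocket, cond, sampler, result.model,
                       start=np.zeros(3), rng=rng)
        fp = interaction_fingerprint(pocket, detect_interactions(pocket, mol)) \
            if len(mol.atoms) else 0 * reference_fp
        sims.append(interaction_similarity(reference_fp, fp))
    return float(np.mean(sims))

print(f"mean interaction similarity, reference condition: "
      f"{mean_similarity(condition, 100):.3f}")
print(f"mean interaction similarity, masked condition:    "
      f"{mean_similarity(mask_condition(condition), 200):.3f}")
```

Output:

```
final reconstruction loss: 1.32 (epoch 1: 29.52)
mean interaction similarity, reference condition: 0.660
mean interaction similarity, masked condition:    0.260
```

The two sites are indistinguishable by atom features alone, so the gap
(0.66 vs 0.26) measures exactly how much the interaction condition steers
generation toward the requested site: conditioned molecules reproduce the
reference hydrogen-bond pattern two and a half times more faithfully than
unconditioned ones.

There is also a command-line interface:

```sh
pocketforge fixtures --n 8 --seed 7 --out-dir fx        # synthetic complexes
pocketforge profile fx/complex000_pocket.pdb \
    --ligand fx/complex000_ligand.sdf --out-prefix p0   # conditions + contacts
pocketforge train --manifest fx/manifest.tsv --seed 3 --out model.npz
pocketforge generate --pocket fx/complex000_pocket.pdb --checkpoint model.npz \
    --condition fx/complex000_condition.tsv --n 20 --seed 9 --out gen.sdf
pocketforge evaluate gen.sdf --out report.tsv
```

## Layout

| Module | Role |
| --- | --- |
| `pocketforge.complex_io` | PDB/SDF I/O, pocket extraction, featurization |
| `pocketforge.profiler` | interaction detection, conditions, fingerprints |
| `pocketforge.model` | invariant embedding, VAE heads, losses |
| `pocketforge.trainer` | trajectory sampling, teacher-forced training |
| `pocketforge.sampler` | sequential atom placement, bond perception |
| `pocketforge.evaluation` | scaffolds, interaction geometry, selectivity |
| `pocketforge.fixtures` | synthetic motif complexes (the test bed) |
| `pocketforge.cli` | `pocketforge` command-line entry point |

See `docs/methods.md` for the model, its assumptions, and the numerical
choices.
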