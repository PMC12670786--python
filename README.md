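# platrand

Randomization machinery for **platform trials** — master-protocol studies in
which investigational arms share a control, are added and closed over time,
and are often allocated in *unequal* ratios (for example the square-root rule
`1:1:…:1:√K` that maximizes the joint power of K comparisons against a shared
control).

The package is aimed at trial statisticians and methodologists who need to

- generate randomization schedules for unequal target ratios while keeping
  the realized allocation close to the target at **every** interim point, not
  just at block boundaries;
- verify that a procedure is **allocation-ratio preserving (ARP)**: that the
  *unconditional* probability of each arm equals the target proportion
  `ρ_j = r_j / Σ r_k` at every allocation step. Non-ARP procedures invite
  selection and evaluation bias even in double-blind trials and reduce the
  power of re-randomization tests;
- operate a live platform: add an arm to an in-flight schedule, close or
  reopen arms, change ratios with clean segment bookkeeping, randomize
  participants with differing eligibility (two-step batch schemes,
  skip-and-backfill), and allocate under constrained drug supply at centers.

## Methods

| class / function | method |
| --- | --- |
| `CompleteRandomization` | i.i.d. draws at `ρ` |
| `PermutedBlock` | uniform block permutations of composition `Q_1..Q_K` |
| `map_equal_to_unequal` | ARP expansion of an equal-allocation rule over `S = ΣQ_j` "fake" arms pooled into `K` arms |
| `HanMinimization` | two-arm unequal minimization with a biased coin — the classical **non-ARP** comparator |
| `BrickTunnel` / `BrickTunnel2` | brick tunnel randomization (BTR) |
| `btr_sqrt_control` | `K:√K` pooled BTR + inner permuted block, for `1:…:1:√K` designs |

**Brick tunnel randomization** confines every allocation path to the chain of
unit lattice cells pierced by the allocation ray `(iρ_1, …, iρ_K)`, so

    |N_ij − i·ρ_j| < 1   for every arm j and every step i,

where `N_ij` is the j-th arm total after `i` allocations — while the
conditional probabilities are derived (here by exact rational linear
programming, step by step) so that the unconditional allocation probability
of each arm equals `ρ_j` at every step.

The diagnostics module computes, **exactly** (rational arithmetic, forward
dynamic programming over the procedure's internal chain):

- the unconditional allocation profile and the ARP verdict (`is_arp`),
- the distribution of arm totals at any step (`state_probabilities`),
- the distribution of the Euclidean imbalance
  `Imb_i = sqrt(Σ_j (N_ij − iρ_j)²)` (`imbalance_tail`, `tail_curve`),
- an independent exhaustive path-enumeration oracle (`exhaustive_oracle`).

## Worked example

A `1:1:√2` target (two treatments vs. a √2-weighted control) approximated by
`5:5:7` (block size 17). After 10 participants:

```python
>>> import platrand as pr
>>> ratio = pr.normalize_ratio((5, 5, 7))
>>> btr = pr.BrickTunnel(ratio)
>>> {t: float(p) for t, p in pr.state_probabilities(btr, 10).items()}
{(3, 3, 4): 0.8823529411764706, (3, 2, 5): 0.058823529411764705, (2, 3, 5): 0.058823529411764705}
```

Under BTR only three totals are possible at step 10 — the one nearest the
ideal `(50/17, 50/17, 70/17)` carries probability 15/17 ≈ 0.88, the two
off-ray ones 1/17 ≈ 0.06 each. The comparators spread much wider over the
same three states:

```python
>>> pbr = pr.PermutedBlock(pr.IntegerRatio((5, 5, 7)))
>>> cr = pr.CompleteRandomization(ratio)
>>> [round(float(pr.state_probabilities(pbr, 10)[t]), 2) for t in [(3,3,4),(3,2,5),(2,3,5)]]
[0.18, 0.11, 0.11]
>>> [round(float(pr.state_probabilities(cr, 10)[t]), 2) for t in [(3,3,4),(3,2,5),(2,3,5)]]
[0.08, 0.07, 0.07]
```

i.e. 0.40 and 0.21 total probability of landing near the target ratio,
versus 1.00 for BTR. And the ARP check:

```python
>>> pr.is_arp(btr, 12)
(True, 0.0)
>>> pr.is_arp(pr.HanMinimization(pr.normalize_ratio((1, 2))), 9)
(False, 0.4866666666666667)
```

the minimization's unconditional probability of arm 1 swings between ~0.1
and ~0.8 across the first steps instead of staying at 1/3.

The same is available from the shell:

```sh
platrand generate --procedure btr --ratio 5:5:7 --n 100 --seed 7 --out schedule.csv
platrand diagnose --procedure btr --ratio 5:5:7 --at 10 --states-out states.csv
```

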