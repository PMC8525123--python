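# assemblage

Null-model toolkit for quantifying stochastic vs. deterministic assembly of
microbial communities from 16S amplicon data (ASV tables), built around the
study design of oil-amendment seawater microcosms: seven treatments sampled
over 28 days in triplicate.

Community ecology asks whether the taxa in a sample are there because of
*selection* (deterministic niche processes) or because of *dispersal, drift
and chance* (stochastic processes).  No single statistic answers this, so
the toolkit implements six complementary null-model frameworks and reports
their consensus:

| model | question | statistic |
|---|---|---|
| NST | how stochastic is assembly overall? | normalized stochasticity ratio, 0% = deterministic, 100% = stochastic |
| Hill null | does turnover between time points exceed chance? | qd dissimilarity over diversity orders q vs. 999 randomizations |
| beta-null deviation | niche or neutral? | observed − expected beta diversity (Bray–Curtis / generalized UniFrac) |
| QPE | *which* process dominates? | βNTI (±2) + Raup–Crick (±0.95) → five process categories |
| competitive lottery | do genus groups have lottery winners? | winner prevalence (>90% rule) vs. broken-stick null, winner diversity |
| phylogenetic dispersion | are new recruits close relatives? | dispersion parameter D of a logistic recruitment model (D<0 = "nepotism") |

A synthetic community generator (`assemblage.synth`) produces ASV tables,
taxonomies and ultrametric phylogenies under known assembly regimes —
neutral, homogeneous/variable selection, dispersal limitation, lottery,
dispersion-controlled recruitment — so every model is validated by
recovering the regime it was fed.  See `docs/methods.md` for the models,
their assumptions, and all numerical choices.

## Worked example

```python
from assemblage import synth
from assemblage.nst import nst_score
from assemblage.qpe import classify_processes

tree = synth.generate_tree(50, seed=42)
neutral, _ = synth.generate_regime_dataset(
    tree, "neutral", n_samples=9, depth=10_000, seed=1, sad_sigma=1.5)
selected, _ = synth.generate_regime_dataset(
    tree, "homogeneous_selection", n_samples=9, depth=10_000, seed=1,
    sad_sigma=1.5, niche_width=0.2, trait_delta=0.3)

for name, ds in [("neutral", neutral), ("selection", selected)]:
    r = nst_score(ds.table, metric="ruzicka", algorithm="PF", n_rand=1000, seed=3)
    print(f"{name:10s} NST = {100 * r.nst:.0f}%")

# QPE needs samples that occupy a modest fraction of a larger pool
tree400 = synth.generate_tree(400, seed=11)
homsel, _ = synth.generate_regime_dataset(
    tree400, "homogeneous_selection", n_samples=9, depth=500, seed=101,
    sad_sigma=0.5, niche_width=0.3, occupancy=0.5, trait_delta=0.3)
profile, _ = classify_processes(homsel, n_rand=99, seed=5)
print("modal process:", profile.modal, f"({profile.fractions[profile.modal]:.0%} of pairs)")
```

prints

```
neutral    NST = 95%
selection  NST = 20%
modal process: homogeneous_selection (92% of pairs)
```

Nine replicate communities drawn from one regional pool are almost fully
stochastic by the NST criterion (95%: observed pairwise similarity matches
the null expectation), while communities assembled under a shared narrow
niche drop to 20% — strongly deterministic — and on the sparser 400-taxon
scenario QPE attributes 92% of sample pairs to homogeneous selection
(βNTI < −2).

## The analysis pipeline

Numbered drivers under `analysis/` run the whole study on a simulated
7 × 5 × 3 design with a known regime per treatment and write tab-separated
tables under `results/`:

```
analysis/01_simulate.py    # the design + generative truth  -> results/data/
analysis/02_nst.py         # NST per treatment (PF and PP)  -> results/nst.tsv
analysis/03_hill.py        # qd vs null per treatment       -> results/hill.tsv
analysis/04_betanull.py    # UniFrac null-deviation curves  -> results/betanull.tsv
analysis/05_qpe.py         # process profiles per treatment -> results/qpe.tsv
analysis/06_lottery.py     # winner prevalence/diversity    -> results/lottery.tsv
analysis/07_phylodisp.py   # dispersion parameter D         -> results/phylodisp.tsv
analysis/08_consensus.py   # all six verdicts side by side  -> results/consensus.tsv
```

The same computations are available as a CLI for arbitrary datasets
(tab-separated counts/taxonomy/metadata + Newick tree):

```bash
assemblage simulate --regime lottery --n-taxa 120 --seed 4 --out data/
assemblage nst --data data/ --metric ruzicka --algorithm PF --n-rand 1000
assemblage run --config run.yaml --data data/ --out results/
```

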