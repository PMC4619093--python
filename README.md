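# gmrsd-context

Comparative-genomics toolkit for **GmrSD-family Type IV restriction
systems** — modification-dependent endonucleases that cleave glucosylated
hydroxymethylcytosine (glc-HMC) DNA.  A GmrSD system is built from two
domains, GmrS (PFAM DUF262, a ParB/Srx-fold NTPase and putative nuclease)
and GmrD (PFAM DUF1524, an HNH-family endonuclease), occurring either fused
into one double-domain protein or as two separate single-domain proteins.

The package is written for bioinformaticians studying restriction systems,
defense islands and domain coevolution.  It provides, as a tested reusable
pipeline, the analyses typically assembled ad hoc for such studies:

* **Domain architectures** — filter domain hits (E-value < 0.001, model
  coverage > 0.8), classify proteins into GmrS-only / GmrD-only /
  double-domain / other, build per-genome inventories, and merge each
  genome's lone GmrS-only + lone GmrD-only proteins into double-domain-like
  pseudo-fusions.
* **Alignment merging & motifs** — merge two family alignments sharing a
  double-domain backbone (equal-length gap stretches inserted identically
  into every backbone row), per-column conservation profiles with the strict
  "> 95 % of sequences" mark, and degenerate-motif scanning for the GmrS
  signature `(I/V)(I/V)DGQQRLTT(I/L/V)xLL` and the GmrD motifs
  `(I/L/V)(E/D)H(I/L/V)xPQ`, `L(G/A)NLxLLxxxN`, `NxxFxxKK` and the weak
  W-motif.
* **Defense-island enrichment** — neighborhoods of ±k ORFs (k = 10) around
  focal genes; top-scoring non-overlapping domain hits; for each of the *M*
  domains a confidence interval for the difference of proportions
  p₁ − p₂ (neighborhood vs proteome background) at the Bonferroni-adjusted
  individual level 1 − α/M, using the continuity-corrected two-proportion
  interval

      (p̂₁ − p̂₂) ± [ z₍₁₊ℓ₎⁄₂ · √(p̂₁(1−p̂₁)/n₁ + p̂₂(1−p̂₂)/n₂) + CC ],
      CC = min( ½(1/n₁ + 1/n₂), |p̂₁ − p̂₂| )

  A domain is called **enriched** when the whole interval lies above zero;
  domains are ranked by the CI lower bound.
* **Coevolution** — collapse splits with SH-like support < 0.8 into
  polytomies, prune leaves without a GmrS↔GmrD counterpart, and score
  tanglegram congruence as the Robinson–Foulds distance over non-trivial
  splits (polytomies compared as observed), plus tanglegram data export.
* **Synthetic data** — generators for annotated genomes with planted
  neighborhood enrichment, protein families with planted motifs at known
  coordinates, and tree pairs derived by a controlled number of SPR moves,
  so every stage is testable against ground truth.

## Worked example

Plant one domain (`D007`) at 5× odds inside the ±10-ORF windows of 100
synthetic genomes (50-domain vocabulary) and run the enrichment analysis:

```python
from gmrsd_context import GenomeSimSpec, simulate_genomes, neighborhood_enrichment

spec = GenomeSimSpec(n_genomes=100, domain_vocab_size=50,
                     enriched_domains={"D007": 5.0}, seed=1)
sim = simulate_genomes(spec)
table, results, windows = neighborhood_enrichment(
    list(sim.genomes), sim.hits_by_protein, sim.focal_proteins, k=10)
```

Printing the window count and the top three results gives:

```
windows: 100, neighborhood instances n1 = 1813, background instances n2 = 6100
rank 1: D007  p1=0.0932 p2=0.0410 diff=+0.0522  CI(level 0.999) = [+0.0278, +0.0766]  enriched=True
rank 2: D036  p1=0.0221 p2=0.0172 diff=+0.0048  CI(level 0.999) = [-0.0082, +0.0179]  enriched=False
rank 3: D024  p1=0.0204 p2=0.0166 diff=+0.0039  CI(level 0.999) = [-0.0087, +0.0164]  enriched=False
```

The planted domain appears in 9.3 % of the 1,813 neighborhood domain
instances against a 4.1 % proteome background; with M = 50 domains each CI
is computed at level 1 − 0.05/50 = 0.999, and only `D007`'s interval lies
entirely above zero, so it is the single enriched call and ranks first.

The same analyses are available from the shell:

```bash
gmrsd-context run --out run1 --seed 1     # full synthetic pipeline, 7 stages
gmrsd-context report --run run1           # inventory / enrichment / motif / congruence summary
gmrsd-context enrich --orfs orfs.tsv --domains domains.tsv \
    --focal truth.json --k 10 --alpha 0.05 --out enrichment.tsv
```

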