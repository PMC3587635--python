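# ssrmir

Mining microsatellites and microsatellite-bearing pre-miRNA candidates in
plant transcriptome unigenes.

De novo transcriptome assemblies of non-model plants yield large sets of
unigenes whose non-coding fraction can harbour regulatory small RNAs.
`ssrmir` implements the in-silico route from such a unigene FASTA to a
catalogue of simple-sequence-repeat (SSR)-bearing pre-miRNA candidates,
for researchers who want that screen as reusable, tested code rather than
a chain of web tools:

* **SSR mining** — every maximal perfect tandem repeat of a primitive
  2-5 nt motif with ≥ 5 iterations, with motif-class and iteration
  summaries and density per Mb;
* **pre-miRNA screening** — 120-nt windows on both strands are folded
  with a built-in Zuker-style minimum-free-energy model and accepted iff
  they (1) form a hairpin holding a 20-22 nt mature miRNA in one arm,
  (2) show < 6 mature/miRNA\* mismatches, (3) fold in −57…−32 kcal/mol,
  (4) have 30-70% A+U, and (5) carry no large loop or break in the
  mature span;
* **target prediction** — gap-free antisense scanning scored WC = 0,
  G:U = 0.5, mismatch = 1; pass requires total ≤ 3, a near-perfect seed
  (positions 2-6), perfect Watson-Crick pairing at the cleavage site
  (positions 10-11), ≤ 2 consecutive disruptions and duplex energy
  ≤ −30 kcal/mol;
* **positional statistics** — each SSR is classified
  upstream/within/downstream of each candidate in the candidate's
  orientation, with an exact binomial test of the downstream bias;
* **expression** — RPKM = 10⁹·C/(N·L) and low/moderate/high/very-high
  tiers;
* **synthetic data** — a seeded generator that plants SSR tracts,
  compliant hairpins, criterion-violating decoys, engineered target
  sites and read counts with exact truth tables, so the whole pipeline
  is testable without any download.

The scientific background and every numeric convention are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Generate a small planted transcriptome and run the full pipeline:

```bash
ssrmir all --seed 7 -o demo/
```

`demo/` then holds the simulated FASTA with its truth tables plus one
report per stage. The candidate table (`demo/candidates.tsv`) follows the
standard report layout — free energy as an unsigned magnitude, positions
1-based inclusive, A+U of the mature sequence to two decimals:

```
unigene_id  ssr_motif  pre_mirna_position  delta_g  direction  mature_position  mature_sequence       au_content
synth00001  CCA        241-360             56.44    Minus      313-332          UAAACAAGAGAGAUUGUGGA  65.00
synth00002  TTA        141-260             55.31    Plus       161-180          CCGACAGGUUCCUGAAUGAG  45.00
```

Reading the first row: on transcript `synth00001` the screen accepted a
120-nt window (positions 241-360) on the minus strand folding at
−56.44 kcal/mol, whose best mature placement (313-332, 20 nt, 65% A+U)
sits in one hairpin arm with fewer than six star mismatches; the
transcript also carries a CCA microsatellite. The run logs its funnel to
stderr:

```
discovery funnel: transcripts=40 -> windows_evaluated=1336 -> windows_accepted=96 -> candidates=20
```

`demo/targets.tsv` lists
the antisense hits that survived the complementarity filter sorted by
duplex energy, `demo/position_summary.json` the
upstream/within/downstream counts with the exact binomial p-value, and
`demo/expression.tsv` the RPKM value and tier per gene.

The same stages are available as a library:

```python
from ssrmir import read_fasta, find_ssrs_all, discover

transcripts = read_fasta("unigenes.fasta")
hits = find_ssrs_all(transcripts)
candidates, funnel = discover(transcripts, ssr_hits=hits, ssr_bearing=True)
```

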