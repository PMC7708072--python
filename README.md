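# pamscreen

Determining the protospacer adjacent motif (PAM) of a Cas9 nuclease, and
measuring its genome-editing activity, from sequencing data. `pamscreen` is
aimed at groups characterising new Cas effectors: it analyses randomized-PAM
depletion screens (plasmid interference in bacteria, or in vitro cleavage of
a 7N library), quantifies indels at edited loci from targeted amplicon
sequencing, and reconstructs the processed crRNA/tracrRNA species from
small-RNA fragment coordinates. Every input can also be *simulated* with
known ground truth, so the whole pipeline is testable end to end without any
sequencing run.

## The statistics at the core

A 7N library carries all 4⁷ = 16,384 PAM variants next to a fixed
protospacer. After exposure to the nuclease, cleavable variants are depleted
relative to an unexposed control. Per variant the package computes

```
Dcoef = log2( (N_sel / N_ctl) · (n_ctl / n_sel) )
```

(`n` variant read counts, `N` sample totals; positive = depleted) and a
one-sided Pearson chi-square on the 2×2 variant-vs-rest table (df = 1, no
continuity correction), calling a variant significantly depleted at
p < 10⁻¹². The depleted set yields a position frequency profile with
per-position information content (the logo quantities), an IUPAC consensus
string, and a Krona-style PAM wheel whose sector areas encode relative
depletion of sub-PAMs (positions 5–7 by default).

Editing activity is quantified CRISPResso-style: merge read pairs, discard
reads with substitutions in the primer footprints, globally align to the
reference amplicon, and call a read modified iff an insertion or deletion
overlaps a 20-bp window centred 3 nt from the guide's 3′ end (the Cas9 blunt
cut). Net editing subtracts the untransfected control; replicate
significance uses an exact one-tailed Mann–Whitney U test.

See `docs/methods.md` for the full model descriptions, parameter defaults,
and limitations.

## Worked example

The built-in demo simulates a screen against the hidden rule `NNNNRTN`
(cleavage probability 0.95, uniform library, 2×10⁶ reads per sample), runs
the full count → stats → profile → consensus → wheel chain, then simulates
a 20%-edited amplicon sample with an unedited control and quantifies it:

```
$ pamscreen demo --outdir demo_out --seed 1
screen consensus: NNNNRTN
net indel %: 19.20
```

What those numbers mean:

* `screen consensus: NNNNRTN` — of the 16,384 PAM variants, 2,048 were
  called significantly depleted (exactly the variants matching the hidden
  rule: any base at positions 1–4 and 7, A/G at 5, T at 6), and the
  consensus read off their position profile reproduces the rule string.
  The intermediate files are in `demo_out/screen/`: `counts.tsv` (per-PAM
  counts), `stats.tsv` (Dcoef, chi-square, p, depleted flag per variant),
  `profile.json`, `wheel.txt`/`wheel.json`.
* `net indel %: 19.20` — from 2,000 simulated read pairs at true modified
  fraction 0.20, the windowed quantifier measured 19.20% modified reads in
  the treated sample and 0.00% in the control (sampling error; the
  binomial 3σ band around 20% at this n is ±2.7). The indel size spectrum
  is in `demo_out/indel/indel_summary.json`.

Each stage is also available separately (`pamscreen simulate | count |
stats | model | wheel | indel | rna`) and as library functions
(`pamscreen.simulate_screen`, `pamscreen.call_depleted`,
`pamscreen.call_consensus`, `pamscreen.quantify_sample`, ...).

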