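# recascan

Analysis pipeline for single-molecule experiments in which a RecA
nucleoprotein filament (NPF) searches for sequence homology inside a
DNA-origami frame, imaged by high-speed AFM.

## The experiment and the problem

A rectangular DNA-origami frame suspends three 128-bp duplex DNA molecules
between anchor points: a heterologous **Control** strand, the **NPF**
strand carrying a 30-nt single-stranded 3′ region on which RecA
polymerises, and a **Reaction** strand whose top strand repeats the 30-nt
probe sequence (identical sequence, parallel orientation). A polarity
marker at one frame corner fixes the orientation, so every AFM image can be
read in sequence coordinates. After UV release, the filament samples the
duplexes; sequential AFM frames record where the NPF intersects a duplex
and for how long. Contacts persisting < 10 s are *transient sampling
events*; long-lived contacts are stable synaptic joints.

Because each RecA monomer reads 3 nt, transient contacts are expected
wherever probe and duplex share at least 3 nt of *micro-homology*. This
package provides, as a tested library plus CLI:

- **`sequences`** — maximal exact-match scanning between probe and target
  (≥ 3 nt, maximal, merged to target loci), plus the two control edits:
  shuffling a domain to destroy it, and switching one domain's sequence to
  another's.
- **`geometry`** — nm ↔ nt conversions with B-form rise 0.34 nm/nt and the
  RecA extension factor (≤ 1.5×): a 30-nt filament spans 10.2–15.3 nm, the
  upper bound being the axial equivalent of 45 nt; `max_monomers(30) = 10`.
- **`imaging`** — synthetic AFM rendering of the frame and vectorization of
  images into labelled strand traces; `intersection_position` measures the
  NPF–duplex contact as arclength along the target from the end furthest
  from the polarity marker.
- **`events`** — transient/stable classification (10 s threshold),
  probe-dislocation artifact flagging, position histograms in sequence
  coordinates, synaptic-joint length statistics against the 10.2–15.3 nm
  band, and frame-outcome proportions with binomial / replicate
  uncertainties.
- **`stats`** — a permutation test for enrichment of transient-event
  positions at micro-homology domains (fraction of events within a
  tolerance of any domain; circular-shift or independent-resampling null,
  both conditioned on the excluded homology region).
- **`synthetic`** — generators for complete experiments with known ground
  truth: sequences with exactly the planted domains, event mixtures with a
  1–2 nm measurement-noise budget, joints, outcomes, and rendered images.

## Worked example

```sh
recascan simulate --outdir demo --seed 7
recascan report --indir demo --seed 7 --n-perm 5000
```

prints (abridged):

```
recascan report (200 events, 500 joints, 514 frames)

micro-homology domains (outside designed homology region):
  nt 3-5  ACG
  nt 10-12  TAC
  ...
  nt 118-121  CCTC

modal event position: nt 55 (count 13)

joint lengths: mean 11.3 nm, sd 3.4 nm, 37% below lower bound

frame outcomes:
  homologous     50.4% (+/- 2.2% binomial SE)
  heterologous    9.1% (+/- 1.3% binomial SE)
  none            5.1% (+/- 1.0% binomial SE)
  unclassified   35.4% (+/- 2.1% binomial SE)

enrichment of transient events at micro-homology: statistic 0.900, p = 0.3279 (5000 permutations)
```

Reading the numbers: the nine listed domains are the 3–5-nt probe
substrings planted outside the designed homology region, and the scanner
recovered exactly those nine by re-scanning the generated strands. The
modal event position (nt 55, ≈ 18.7 nm from the origin end) is the centre
of the designed homology region, where stable joints form. Joint lengths
centre inside the 10.2–15.3 nm band expected for a 30-nt filament at
partial RecA coverage; the fraction below 10.2 nm corresponds to partially
aligned filaments. The outcome percentages recover the generator's rates
(52.5 / 7.4 / 4.6 / 35.5%) to within binomial error at n = 514. The
enrichment p-value at a single-experiment event count (200) is weak — with
nine domains on the 98 non-homology positions and ≈ 1.6 nm measured peak
width the per-event contrast is small; pooling events across experiments
(≈ 1000) makes the planted signal decisive (see `docs/methods.md`).

A scan alone:

```sh
recascan scan --fasta demo/sequences.fasta --outdir demo
# -> 9 micro-homology domains -> demo/domains.tsv
```

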