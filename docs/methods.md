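# Methods

This note documents the models and procedures implemented in `nrekit`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer would want to
know about.

## Topology model

Every protein is placed in exactly one of three groups from its feature
annotations:

- **RK** — has an annotated extracellular domain (ECD) *and* a TM helix;
- **RLCK with TM** — TM helix, no ECD, and an extracellular stretch of
  fewer than `extracellular_max_len` residues (default 60, i.e. 180
  coding nucleotides) N-terminal of the first TM helix, minus any
  annotated signal peptide;
- **RLCK without TM** — no TM helix;
- anything else (e.g. a long ECD-less extracellular stretch) is
  `unclassified` rather than guessed.

ECD presence comes strictly from annotations; no ECD inference is
attempted, because domain recognition belongs to upstream tools whose
coordinates this package consumes.

**TM consensus.** When TM intervals from several prediction sources are
available, an interval corroborated by a second source (pairwise overlap
≥ 5 residues) is reported as the intersection of the pair — the most
conservative reconcilable span. Uncorroborated intervals pass through
flagged `single_source`. The rule is symmetric in its sources and
idempotent.

**Hydropathy fallback.** For proteins with no TM annotation at all, a
single-pass detector marks maximal runs of positions whose centred
19-residue window mean of Kyte–Doolittle hydropathy (values from
biopython) reaches 1.6, keeping runs of at least 15 residues. These
thresholds make the detector deliberately *precise rather than
sensitive*: a textbook 21-residue helix flanked by charged residues sits
near the decision boundary and is found only when strongly hydrophobic.
The fallback never overrides provided annotations; pipeline guarantees
(exact topology recovery) are stated for annotated inputs.

## NRE boundaries

The NRE C-terminal boundary is the residue immediately before the kinase
domain; the N-terminal boundary is the residue after the TM helix (JM) or
the protein start after any annotated signal peptide (NKE). Signal
peptides are excluded from NKEs so secreted-leader residues are never
counted as regulatory sequence.

The kinase-domain start is *refined* rather than taken on faith: plant
RLK kinase domains carry a conserved `(L/I/V)GXG` 4-mer occupying
positions 5–8 of the domain (the glycine-rich-loop region). Candidate
starts `d` within ±30 residues of the annotated start are scored for an
anchor match at `d+4`; the candidate nearest the annotation wins, ties
going to the smaller coordinate (deterministic, annotation-respecting).
With no candidate the annotated start is used and the boundary is marked
unrefined, preserving both behaviours for audit. Empty NRE intervals are
counted, and a TM helix reaching into the kinase domain raises a
boundary-conflict error carrying both coordinates.

Before motif analysis the last `cterm_strip = 14` residues — the
conserved consensus block — are removed; segments that would vanish are
counted, not erred on.

## Profiling

- **Scaled composition.** Each length-`L` segment is rescaled onto
  `scale_bins = 200` positions: residue `i` spreads its unit mass
  uniformly over the fractional bin interval `[(i−1)·200/L, i·200/L)`.
  This conserves total mass exactly (grand total = Σ segment lengths,
  asserted to 1e-6) and is length-unbiased; nearest-bin rounding would be
  neither. Residue-weighted by default; per-sequence weighting
  (each segment total mass 1) is an option.
- **Terminal logos.** Frequencies over the first/last
  `terminal_window = 20` residues; per-column information content
  `IC = log2 20 − H` in bits, without small-sample correction — intended
  use is large `n`, and `n` is reported alongside so users can judge.
  Degenerate letters spread fractionally over their expansion sets
  (B={D,N}, Z={E,Q}, J={I,L}, X=all 20).
- **14-aa signature.** The consensus `F S Y E E L E K A T [D/N] N F
  [S/D]` is searched in the C-terminal 40 residues; the best ungapped
  placement is a hit at ≥ 10/14 positional agreements (threshold
  configurable, reported with every hit). The ST motif flag reads T at −5
  and F at −2 of the *segment* (−1 = last residue); this negative-offset
  convention counts leftward from the segment end throughout, which is
  also how the LRR-VI-2 rule is stated.
- **LRR-VI-2 two-type rule.** Type 1 requires S at −28 *and* a scan match
  of the class motif; anything else — including segments too short to
  reach −31, which are flagged — is type 2.

## Motif model

**PWMs.** Column counts (fractional for degenerate letters) plus a
per-column pseudocount of 0.1 distributed in proportion to the
background; log-odds are base-2 against the corpus background (letter
frequencies over all trimmed segments, +1 pseudocount per letter). The
consensus letter is the column argmax, replaced by B/Z/J when the
runner-up is within 0.8× of the maximum and the pair has a degenerate
code.

**Exact scan p-values.** Per-cell log-odds are integerized to multiples
of `resolution = 1e-3` bits; the distribution of the integer total of a
random background word is built by exact convolution column by column, so
the reported tail probability equals brute-force enumeration for *any*
word, and per-word score distortion is bounded by `width · resolution /
2`. Scanning scores every offset, keeps `p ≤ scan_p` (default 0.001), and
collapses overlapping matches of one motif to the best-p occurrence
(leftmost on ties). Degenerate letters in sequences score as the
background-weighted mean over their expansion sets.

**ZOOPS-EM discovery.** Each sequence carries at most one site: with
probability γ a site sits uniformly at one of its `L−w+1` offsets,
otherwise the sequence is background. The E-step computes per-offset
posterior occurrence probabilities; the M-step re-estimates the PWM (with
a background-proportional Dirichlet pseudocount) and γ, restricted to
sequences long enough to carry the motif. The penalized (MAP) objective
is asserted non-decreasing every iteration, with a 1e-7 relative
tolerance for accumulated floating-point error in the log-sum-exp sums.
Runs start from `n_starts = 8` k-mer windows sampled from the data
(deterministic given the seed); converged fits then undergo
**column-shift refinement** — re-seeding EM from the posteriors with
windows moved by ±1…3 columns and keeping improvements — which escapes
the off-by-one alignment optima that plain EM is prone to. Candidate
widths are scanned over `width_range` and ranked by the significance of
the log-likelihood-ratio statistic `2·ΔLL` under a chi-square with
`19·w + 1` degrees of freedom; models with `p > discovery_p` (default
0.005) are discarded. This chi-square calibration preserves the threshold
semantics of the reference discovery tool but does not replicate its
E-value computation — an intentional, documented deviation. For multiple
motifs, positions under probable sites are probabilistically damped
(log-erasure weights) before the next motif is sought. Everything is
bit-reproducible given the seed.

Discovery can also be run per class (`discover_per_class`), which
characterizes one motif per class the way class-specific motifs are
reported; corpus-wide discovery with several motifs on a multi-class
corpus can legitimately converge to blends of similar planted motifs,
which the downstream identity and S/T/Y screens then flag.

## Enrichment and conservation

The analyzed corpus for enrichment is the **domain-free** NRE set:
segments overlapped by an `other_domain` annotation are excluded from
both `Nc` and `Ntotal`. This choice is forced by arithmetic — the
published per-class normalized frequencies reproduce only with the
domain-free total (457,685), which the acceptance script and tests verify
for seven printed rows.

`Nm` and `P` count *occurrences* (matches), not distinct sequences;
per-class occurrence sums are asserted to equal `P` corpus-wide. The
statistic `F = Nm²·Ntotal/(P·Nc²)` is computed in both its product and
factored forms and cross-checked to 1e-9 on every call. Calibration: if a
motif occurs exactly once per segment in every class, `F = 1` for every
class; more generally, a uniform per-segment occurrence rate `r` in all
classes gives `F = r`, and proportional allocation of a motif's
occurrences gives `F = P/Ntotal` — so the `F > 1` filter (strict
inequality) selects class concentration beyond one-per-segment
uniformity. Species presence counts distinct species with ≥ 1 match.

Phosphosite containment is inclusive on both match boundaries; the motif
offset of a contained site is `position − match_start + 1`. Sequence
identity `I` is the fraction of match positions agreeing with the
consensus (degenerate consensus letters agree with any expansion member).
`mean SI` averages over matches; averaging over sequences or species is
exposed as an option only in the sense that callers can pre-filter the
match list. Tiers: mean SI > 80% high; 50–80% inclusive moderate; below,
low. A motif whose consensus lacks S/T/Y at *any* contained-site offset
fails `sty_ok` and is excluded from the phospho-motif report (and
counted). With positionally jittered matches this rule fires often — a
strictness inherent to the containment-then-consensus definition.

## Synthetic-data generator

Each protein is assembled as: optional signal peptide → ECD filler (RKs)
or a short extracellular stretch (RLCKs with TM) → hydrophobic 21-mer TM
helix → NRE → 60-residue kinase-domain stub whose residues 5–8 are a
planted `(L/I/V)GXG` anchor. The NRE is a basic (R/K) 6-residue run, a
serine-enriched middle (serine rate 0.25) optionally carrying the class
motif with per-position substitution noise, a one-residue spacer, and the
14-aa consensus tail with configurable [D/N] (0.7/0.3) and [S/D]
(0.6/0.4) variant probabilities. Placing the motif directly before the
spacer+tail puts the LRR-VI-2 motif's serine at segment position −28 and
its threonine at −31, matching the two-type rule's geometry.

Study conditions baked into the defaults: topology mix 0.61/0.09/0.30
(the family-wide proportions of RKs, RLCKs with TM, and cytoplasmic
RLCKs), NRE lengths from an equal mixture of normals with modes 40 and 50
(sd 8) — the observed length peak — resampled into the feasible range,
planting rate 0.8 and substitution rate 0.1, six species, 250 proteins
per class across four classes whose planted motifs and phospho offsets
follow published class motifs (e.g. the LRR-VI-2 21-mer with pT at offset
6 and pS at offset 9).

The region around the kinase-domain start is rejection-sampled so that
exactly one anchor candidate exists within ±45 residues, making boundary
refinement well-posed even under ±10-residue annotation jitter; the stub
filler avoids G and I/L/V to keep the rejection cheap — the stub is a
scaffold, not a realistic kinase, because only the anchor and length
matter to the pipeline under test. Phosphosites are emitted at declared
motif offsets when the (possibly noised) residue is still S/T/Y; optional
background sites exercise the non-containment and S/T/Y-exclusion paths.
The `corrupt` harness jitters kinase starts and drops TM annotations
without touching truth.

**What passing tests do and do not show.** The generator emulates
letter-level structure only: composition, planted motifs, terminal
consensus, anchors. It makes no attempt at realistic higher-order k-mer
statistics, homology between sequences, alignment uncertainty, or
annotation error models beyond uniform jitter/dropout. Exact recovery on
synthetic data therefore validates the *machinery* (boundary arithmetic,
EM, scan statistics, counting) — not performance on real proteomes, where
annotation quality dominates.

## Problem sizes and runtimes

The test suite and acceptance script use a 1,000-protein corpus for
boundary/topology/enrichment checks, 200 segments for discovery
(recovering a planted 21-mer at ≥ 19/21 consensus positions with site
recall and precision ≥ 0.9), 10,000 random tuples for the formula
equivalence check, and full enumeration (20³ and 4⁸ words) for the
p-value oracle. These sizes were chosen as the smallest at which the
statistical claims are stable across seeds; the whole suite runs in well
under a minute on one CPU.

## Known limitations

- The hydropathy fallback trades sensitivity for precision (see above);
  borderline 21-residue helices are often missed, by design.
- Discovery significance uses a chi-square approximation, not the
  reference tool's E-values; thresholds are comparable in spirit, not in
  calibration.
- Corpus-wide multi-motif discovery can blend similar planted motifs;
  per-class discovery is the robust mode for class characterization.
- The published corpus-scale counts (hundreds of thousands of segments,
  65-motif catalogues, species tallies over hundreds of genomes) depend
  on external genome sets and databases and are out of scope; the
  package validates the statistics and machinery that produced them.
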