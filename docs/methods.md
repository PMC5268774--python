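# Methods

This note documents the models behind `mircatch`, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical conventions that make results reproducible.

## Duplex thermodynamics

Hybridisation of a capture oligo to its target is modelled as a two-state
nearest-neighbor (NN) sum: ΔH° and ΔS° are accumulated over dinucleotide
stacks plus initiation terms, ΔG°₃₇ = ΔH° − 310.15·ΔS°/1000, and

    Tm = ΔH°·1000 / (ΔS°_salt + R·ln(C_T / x)) − 273.15
    ΔS°_salt = ΔS° + 0.368 · N_stacks · ln[Na⁺]

Three parameter sets are shipped as TSV data files with their literature
provenance in the headers: the SantaLucia 1998 unified DNA:DNA set, the
Sugimoto 1995 RNA/DNA hybrid set (keyed on the RNA strand) and the
Xia 1998 RNA:RNA set.

Conventions, and the reasoning where the choice was genuinely open:

* **Concentration term.** The default is the excess-strand convention
  x = 1 with C_T = 0.25 µM, matching the behaviour of the widely used
  commercial oligo calculator that probe-design tables in this field are
  produced with; the equimolar convention x = 4 is available via
  `Conditions(conc_convention="quarter")`.  With the default, the hybrid
  Tm of the published mesothelin oligos is reproduced within 1 °C
  (70.1/76.9/72.4 °C vs printed 70.6/77.9/72.6 °C); the x = 4 convention
  is systematically ~2 °C lower.
* **Which duplex class reports what.** Design reports quote the melting
  temperature from the DNA:RNA hybrid set — the probe is DNA, the target
  is mRNA — but the *hybridisation free energy* (the denominator of the
  self-dimer ratio) from the RNA:RNA set.  This mirrors the calculator
  conventions under which the published screening thresholds were set:
  the printed ΔG values of the mesothelin table (−48.13/−39.24/−48.6
  kcal/mol) agree with RNA:RNA ΔG°₃₇ within 3–7 % but are ~35 % stronger
  than any hybrid-parameter ΔG, while the printed Tm values agree with the
  hybrid set and with no other.  Both classes are exposed through
  `thermo.duplex_thermo` so either can be computed explicitly.
* **Salt correction.** The entropic 0.368·N·ln[Na⁺] form: simple, monotone
  in [Na⁺] (a property tested explicitly), and standard.

### Self-dimer screen

Two copies of the oligo are aligned antiparallel at every ungapped offset.
Within one offset, every maximal run of ≥ 2 Watson–Crick pairs is a helix
scored by DNA:DNA stack energies; an optimal subset of helices is kept,
charging a flat **+2.0 kcal/mol per interior loop** between retained
helices (a coarse average of published DNA internal-loop costs — the model
does not resolve loop size or asymmetry).  The reported ΔG is the minimum
over offsets; "none" means no two adjacent pairs form anywhere.

Alternatives considered: scoring only the single best helix underestimates
dimers with two cooperating helices (the published value for the third
mesothelin oligo, −6.68 kcal/mol, comes from such a structure); summing
all helices with no loop cost overestimates them (−7.98 kcal/mol for the
same oligo, which would push its dimer ratio past the 15 % screening
threshold that the oligo in fact passed).  The flat-penalty model
reproduces all three published dimer values within ±1.0 kcal/mol with a
single fixed constant.  An exhaustive search over offsets and helix
subsets serves as the test oracle.

## RNA secondary structure and accessibility

The folding model is deliberately small so that *every* derived quantity
can be checked against exhaustive enumeration:

* nested structures over Watson–Crick and G:U pairs, hairpin loops ≥ 3 nt,
  no pseudoknots;
* energy = Σ stack terms for directly adjacent pairs (shipped table:
  RNA:RNA ΔG°₃₇-derived values for WC/WC stacks, coarse constants for
  wobble-containing stacks) **plus a flat helix-initiation cost of
  +3.0 kcal/mol per maximal stacked helix**; unpaired bases are free.

The initiation cost plays the role of loop penalties in full energy
models.  Without it, isolated zero-energy pairs proliferate entropically
and essentially every base of a random sequence appears paired in the
ensemble, which defeats the model's purpose of locating accessible
regions.  Because a structure's helix count equals its pair count minus
its stack count, the cost is implemented exactly as a per-pair charge with
every stack bonus shifted by the same amount; the test oracle computes
energies by the independent helix-counting formula.

Algorithms: minimum-energy folding is an interval dynamic program over
integer centi-kcal energies with deterministic tie-breaking (fewest pairs,
then lexicographically smallest dot-bracket); the partition function uses
McCaskill-style inside/outside recursions over the same decomposition,
with per-base rescaling to avoid overflow on windows of a few hundred
nucleotides.  ΔG_open(interval) is the difference of constrained and
unconstrained ensemble free energies and is clipped at zero against
floating-point jitter.  All four quantities (MFE energy, tie-broken
structure, ensemble free energy, per-base unpaired probabilities, opening
costs) are tested to equal brute-force enumeration on hundreds of random
sequences up to 12 nt, and probabilities normalise per base to 1 within
1e−9.

Long transcripts are folded in overlapping windows (default 300 nt,
step 150) with per-base unpaired probabilities averaged over covering
windows — the standard locality trade-off of accessibility-based target
predictors; whole-molecule folds are not attempted.

## Capture-oligo design

Candidates are antisense windows of 22–25 nt (the range spanned by
published capture oligos) whose target interval lies inside a detected
single-stranded region ("contained" mode) or covers ≥ 13 accessible bases
("partial" mode, for oligos straddling short paired interruptions, which
matched the best-performing published oligo).  Screening defaults:
hybrid Tm > 70 °C, self-dimer ratio < 15 %, GC 40–60 %, mean unpaired
probability ≥ 0.5, and a specificity hard-fail only for perfect
complementarity of ≥ (oligo length − 1) to a non-target transcript —
long-but-imperfect matches (14–15 nt) are reported and penalise rank
only, since a single internal mismatch is generally enough to abrogate
capture.  Ranking is a total order (accessibility, then Tm, then
off-target count, then position, then sequence), so reports are
byte-reproducible.

The off-target scan seeds exact k-mers of the oligo's sense-strand
complement and extends ungapped, reporting maximal segments with at most
the configured number of internal mismatches; the seed length is capped by
the pigeonhole bound (min_len − mismatches)/(mismatches + 1) so that no
reportable segment can be missed, and equality with a naive all-offsets
scan is a test, not an assumption.

## miRNA binding-site scoring

Seed classes: 6mer (complement of miRNA positions 2–7), 7mer (2–8) and
8mer (2–8 plus target adenosine opposite position 1); the whole transcript
is scanned, not just the 3′UTR.  Site coordinates are 1-based positions of
the 5′-most paired target base.  ΔΔG = ΔG_duplex + ΔG_open, where
ΔG_duplex is the stacking energy of the ungapped full-length miRNA::site
duplex anchored at the seed (same stack table as the folding model, for
internal consistency) and ΔG_open opens the site ± 15 nt evaluated on a
local context of ± 80 nt.  The scorer is accessibility-aware in the spirit
of whole-transcript target predictors but makes no attempt to reproduce
any particular published predictor's numbers.

## Differential capture statistics

Counts are normalised with median-of-ratios size factors.  Per miRNA,
log2fc = log2((mean_capture + 0.5)/(mean_scrambled + 0.5)); the Wald
statistic log2fc/SE uses a delta-method standard error under the
negative-binomial variance μ + αμ², with α a pooled method-of-moments
estimate shrunk (geometric mean) toward a fitted α(μ) = a₀ + a₁/μ trend;
rows with no evidence of extra-Poisson noise take the trend.  The trend is
fitted across all rows — conditioning on positive moment estimates biases
it upward.  The statistic is referred to a **standard normal**: the SE is
model-based rather than a per-feature sample variance, and simulation
shows the normal reference is calibrated at n = 3 + 3 (null fraction of
p < 0.05 ≈ 0.06) where a t reference with 4 df is far too conservative.
Benjamini–Hochberg adjustment runs across miRNAs with non-missing p;
selection requires adjusted p < 0.1, normalised base mean > 20 (strict,
interpreted as normalised since the source protocol does not specify) and
positive fold change.

Known behaviour worth stating: with one-directional enrichment of ≳ 10 %
of features, median-of-ratios normalisation absorbs part of the signal
(size factors shift ~4 % and fold changes attenuate accordingly).  This is
a property of the normalisation, shared with the standard count-based
tools, not an implementation artefact; the synthetic default therefore
plants balanced enrichment/depletion.

## Synthetic data

`synth_transcript` plants perfect GC-rich inverted repeats (hairpins) and
A/C-only stretches (accessible regions) in a random background.  When
accessible stretches are requested, the background is sampled with no two
adjacent G/U bases: any *stacked* helix recruiting the A/C stretch would
need a GG/GU/UG/UU partner dinucleotide, which then cannot exist, so the
planted ground truth holds by construction (isolated pairs are already
suppressed by the helix-initiation cost).  `synth_counts` draws
negative-binomial counts (variance μ + αμ², gamma–Poisson) with lognormal
per-library depth multipliers (σ = 0.15) and plants enrichment by scaling
capture-arm means; its default shape emulates a small-RNA capture
experiment — 325 miRNAs, three libraries per arm, lognormal baseline
means (median 80), and a minority (~10 %) of the pool redistributed
between the arms, half enriched and half depleted.  `synth_reads` emits
mature-sequence + adapter reads with optional substitution errors and
length jitter.  All generators are bit-reproducible given a seed.

What the generators do *not* emulate: sequencing-error profiles and
ligation bias, isomiR heterogeneity, cross-linking artefacts, and real
transcriptome-scale off-target landscapes.  Passing tests therefore
demonstrate correctness of the algorithms under the stated models, not
performance on any particular real library.

Problem sizes used by the shipped tests and reproduction script: folding
oracles run on sequences ≤ 12 nt (hundreds of random draws); design
demonstrations fold 260-nt transcripts in one window; statistical
calibration uses 500-miRNA null matrices and 100 replicates of 325-miRNA
matrices with 16 + 16 planted; the thermodynamic reproduction values are
exact NN sums over the three published 22–25-nt oligos.

## Numerical conventions and degenerate inputs

Folding energies are integer centi-kcal internally, so minimum-energy
comparison and tie-breaking are exact; partition functions are rescaled
per base by exp(−β·E_MFE/n).  Coordinates in every public interface are
1-based inclusive; U/T are interchangeable on input and normalised per
declared alphabet; N bases never pair and disqualify any oligo window that
overlaps them.  Empty FASTA files, malformed records, overlapping region
annotations, out-of-bounds intervals, all-zero count rows, incomplete
qPCR replicates and Ct values outside (0, 45) raise informative errors
rather than propagating silently.

## Limitations

The folding model is not a Turner-rule folder: no loop-size dependence, no
dangling ends, coarse wobble stacks; it is meant for relative
accessibility, not for reproducing reference-folder energies or exact
structures.  The dimer screen is ungapped with a flat loop cost.  The NB
test is count-model inspired, not a re-implementation of any published
differential-expression package, and its exact gene lists will differ from
those tools.  Off-target scanning is transcript-set scale, not
genome scale.
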