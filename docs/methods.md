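# Methods

## Coordinates and data model

Residue indices are 1-based inclusive on the precursor protein, signal
peptide included; codon `i` encodes residue `i`, so codon indices double
as nascent-chain lengths. Transcript nucleotide positions are 0-based
half-open (BED convention) with position 0 at the first nucleotide of
the start codon; a fixed per-dataset 5′-UTR offset can be supplied
(`cds_start` in the I/O functions, `utr5_nt` in the simulator).
Annotated CDS lengths may include the stop codon
(`3 × (protein_length + 1)`, the simulator's dialect) or not; both are
accepted. Topology is an *input*: each transcript carries ordered,
non-overlapping segments of kind SP / lumenal / TM / cytosolic. The
"translocated" length of a protein is the length of its longest lumenal
segment; TM spans are membrane-embedded and excluded.

## A-site calibration and assignment

Ribosome-protected fragments of a given length have their A-site a fixed
offset downstream of the 5′ end. For each read length we score every
candidate offset in a search window (default 10–15 nt) by the number of
reads whose shifted 5′ end lands in frame 0 of the CDS, and keep the
maximizer; lengths whose best frame-0 fraction falls below
`periodicity_min` (default 0.5) are excluded downstream. Frame counts
are invariant to shifting an offset by 3 nt, so the search window can
contain exact ties; ties are resolved first by the number of reads whose
A-site falls on an in-bounds codon (reads near the start/stop codon
disambiguate the ±3 nt alternatives) and then toward the smaller offset,
keeping the result deterministic. A read with 5′ end `p` and accepted
offset `o` contributes one count to codon `floor((p + o − cds_start)/3) + 1`;
out-of-CDS assignments are dropped and tallied in a QC report, so
accepted in-bounds reads always equal the total matrix mass.

## Transcript-level enrichment

Abundance per library is transcripts-per-million over CDS counts:
`rate_g = n_g / (cds_length_g / 1000)`, `TPM_g = 10^6 · rate_g / Σ_h rate_h`.
Enrichment is `log2((TPM_IP + α)/(TPM_input + α))` computed per
replicate and averaged; the pseudocount α = 0.5 TPM is small and
symmetric to avoid sign bias at low coverage. Averaged enrichment is
median-centred over all quantified transcripts, putting the unengaged
bulk of the transcriptome at zero. Significance per transcript is a
Pearson chi-squared test (1 df, no continuity correction) on the 2×2
table `[[n_IP,g, N_IP − n_IP,g], [n_input,g, N_input − n_input,g]]` with
replicates pooled for power, followed by Benjamini–Hochberg correction
over all tested transcripts; the volcano and length-stratified views are
restricted to the secretory/membrane universe afterwards. Transcripts
with fewer than 32 pooled input reads are neither centred nor tested —
their log-ratios are dominated by the pseudocount and would distort the
centring median. Tables with a zero margin have undefined expected cells
and are flagged untestable (NaN) rather than given a statistic.

## Codon-level profiles and onset detection

The per-codon enrichment is
`e_c = log2((n_IP,c/N_IP + β)/(n_input,c/N_input + β))` per replicate,
with β in per-read rate units; the default β = 0.5/min(N_IP, N_input)
corresponds to half a read in the shallower library, keeping zero-count
codons finite while shrinking toward 0 as depth grows. Replicates are
aggregated as arithmetic mean and range (max − min) per codon; the mean
profile is smoothed with a centred running mean (default window 15
codons, truncated at the profile edges). The window suppresses
codon-level shot noise at realistic depths while bounding the onset
localization error at about half a window.

Onset detection operationalizes "the profile rises and stays up": the
baseline is the mean of the first 50 codons, the plateau the mean of the
top decile of smoothed values, and the onset the first codon exceeding
`baseline + θ·(plateau − baseline)` (θ = 0.5) for at least 10
consecutive codons. If the rise is below 0.5 log2 units no onset is
called. The rule is invariant to adding a constant to the profile, and
every knob (θ, persistence, baseline window, minimum effect) is exposed
in the pipeline config; it is one deliberate operationalization of a
qualitative feature, and calls should be read with the ±window
resolution in mind.

With Δ = 55 residues of nascent chain buried in the ribosome exit tunnel
and SEC61 channel (configurable; the figure is approximate), an onset at
codon L maps to the exposed lumenal window `(sp_end + 1, L − Δ)` — empty
if `L − Δ ≤ sp_end` — and inversely a residue `r` clears the buried
segment at chain length `L = r + Δ`. The two maps are exact inverses on
the in-range domain.

## Synthetic data generator

The generator emulates the *conditions* of a selective-profiling study,
not any particular dataset. Defaults: 300 transcripts (25% secretory,
25% membrane, 50% cytosolic), protein lengths uniform on 120–900
residues, signal peptides 15–30 residues, two replicates, 60,000
expected reads per library (≈200 per transcript per library), log-normal
abundance weights (σ = 1), and one GRP94-like secretory transcript — 803
residues, signal peptide 1–21, lumenal segment 22–803 — pinned as the
most abundant message and targeted by the factor at onset codon 204 with
a four-fold capture gain. Membrane records alternate
lumenal/TM/cytosolic segments (TM fixed at 21 residues) and always carry
at least one TM span at practical protein lengths; cytosolic records
have no translocated segment.

Ribosome occupancy is uniform along each CDS (no pause sites). Input
counts per codon are Poisson with mean proportional to the abundance
weight; IP counts are a Poisson thinning of occupancy with capture
probability `baseline_capture` (default 0.2) before a target's onset and
`baseline_capture × capture_fold` (capped at 1, with a logged warning)
from the onset codon to termination. Both samples are normalized so a
library's expected total equals its configured depth — engagement
manifests as a relative, position-dependent capture gain, as in a real
IP, not as a library-size change. The expected post-onset minus
pre-onset codon-level log2 enrichment is therefore `log2(fold)`. An
optional gamma-mixing knob adds negative-binomial overdispersion
(default off). The magnitude of the capture fold is a free simulation
parameter, not an estimate of the underlying biology.

In `raw_reads` mode each count is expanded into a read with length drawn
from {28–31} nt and 5′ end placed at the per-length A-site offset
({28: 11, 29: 12, 30: 12, 31: 13} nt) upstream of the A-site codon, with
perfect frame fidelity by default and a configurable frame-error rate;
reads that would extend outside the transcript (CDS plus configured
UTRs) are dropped, so round-trip count recovery is exact only when the
UTR margins accommodate the read geometry.

All randomness flows through a seeded generator hierarchy
(`numpy.random.SeedSequence` with fixed spawn keys per purpose, sample
and replicate): one integer seed fully determines the dataset, and
rerunning the pipeline reproduces every output byte for byte.

What the simulator does **not** emulate — and what passing tests
therefore do not demonstrate about real data: rRNA contamination,
alignment ambiguity and multi-isoform assignment, UTR and disome
occupancy, ribosome pausing, position-dependent ligation or coverage
bias, and batch structure between replicates beyond sampling noise.

## Validation strategy

Every statistical primitive (chi-squared statistic, BH adjustment, TPM,
median-centring, A-site offset search) is checked against an independent
brute-force computation on fixtures, and the chi-squared path is
additionally cross-checked against `scipy.stats.chi2_contingency`. A
null simulation (1,000 transcripts, all folds 1, ≈200 reads per
transcript per library) verifies nominal type-I error of the transcript
test, essentially zero BH discoveries, and an exactly-zero centred
median. Parameter recovery runs 50 seeded simulations under the default
conditions and requires the onset call within ±15 codons of truth in at
least 90% of runs and the GRP94-like target in the top 1% of centred
enrichment in every run. Problem sizes in the test suite (tens to a
thousand transcripts, 2×10⁴–2×10⁵ reads per library) were chosen as the
smallest scales at which these stochastic properties are stable.

## Known limitations

* The onset rule is a threshold heuristic, not a changepoint model;
  gradual recruitment ("progressive stabilization") yields an onset that
  depends on θ.
* Enrichment significance treats codon counts within a transcript as
  exchangeable (pooled 2×2 table); strong positional structure makes the
  transcript-level p-value conservative or anticonservative depending on
  direction.
* Offset calibration assumes a single dominant frame per read length;
  heavily degraded libraries violating 3-nt periodicity are excluded by
  design rather than rescued.
* The secretory/TM universe is whatever the annotation declares; no
  topology or signal-peptide prediction is attempted.
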