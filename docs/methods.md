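# Methods

## Scope and model

`pcfam` implements the analysis battery of a genome-wide phytocyanin
(PC) family characterization: rule-based structural classification,
physicochemical profiling, codon-usage-bias statistics, pairwise Ka/Ks,
tandem-cluster detection, promoter cis-element scanning and qPCR
quantification. Because published family surveys of this kind rest on
genome assemblies and external predictor servers that cannot be bundled,
the package is validated end to end on synthetic genomes with planted
ground truth; the synthetic generator is therefore first-class, tested
code, not a fixture.

## Domain detection and classification

The four structural domains are detected by transparent sequence
heuristics (external predictors such as signal-peptide or GPI servers
are deliberately not reimplemented; parity with them is not claimed):

* **SP** — residue 1 is Met and some 8-residue window starting in
  residues 2–25 has mean Kyte–Doolittle hydropathy ≥ 1.6; the span ends
  5 residues after the best window (nominal cleavage region).
* **PLCD** — a complete copper site matches
  `H x(20,90) C x(2,20) H x(2,20) [M|Q]` with non-greedy, leftmost
  non-overlapping semantics; the four ligand slots are reported in
  H < C < H < Z order. An incomplete (ENODL-type) site is a ~70-residue
  window around a disulfide Cys scaffold `C x(2,60) C` containing at
  least two further ligand-like residues but no complete pattern. The
  window is kept tight (40 residues upstream of the scaffold, 20
  downstream) so two adjacent incomplete domains are resolved
  separately.
* **ALR** — the longest merged run of 20-residue windows with ≥ 50%
  P/A/S/T, at least 20 residues long, outside the SP/PLCD/GAS spans.
* **GAS** — mean Kyte–Doolittle of the final 12 residues ≥ 1.5 plus a
  small omega candidate (G/A/S/N/D/C) 15–30 residues from the
  C-terminus.

All thresholds live in `DetectorConfig` and are deliberately wider than
the generator's planted spacings (40/5/5), so the heuristic detectors
face a detection problem, not a string-equality check.

Subfamily follows the copper-ligand rule: no complete site → ENODL; a
complete site ending in Gln → SCL; ending in Met → UCL when an ALR is
present, PLCL otherwise. The eight architecture types are a pure lookup
on (SP, PLCD count, ALR, GAS); types VI and VII are distinguished by
PLCD count (single vs double), the only assignment consistent with the
constraint set (SP absent in VI–VIII, ALR absent in IV/V/VIII, GAS in
I/II/V/VI/VII, two PLCDs in type I). The type table keys on PLCD count
regardless of site completeness, so a two-PLCD ENODL can be type I.
AGP classes: no ALR → non-AGP; types I–II → typical AGP; III/VI/VII →
atypical AGP; chimeric AGP = SP ∧ ALR. Proteins without any PLCD are
reported as non-members, never dropped. Family names are assigned per
subfamily in (chromosome, start) order.

## Physicochemical profile

MW, GRAVY and the instability index use the standard ProtParam formulas
(via Biopython). The theoretical pI solves the Henderson–Hasselbalch
net-charge equation over D, E, C, Y, H, K, R and the termini by
bisection on [0, 14] to |charge| < 1e−4; the charge is strictly
decreasing in pH so the root is unique. The pKa set is the Bjellqvist
table, shipped as a plain dict and swappable per call. Acidity classes
follow the printed convention acidic < 6.5 ≤ neutral ≤ 7.5 < basic (the
boundaries belong to neutral, reading "6.5–7.5" as a closed interval);
the hydropathy dichotomy keys on the GRAVY sign.

## Codon-usage battery

All statistics work on sense-codon counts (stops excluded, codons with
ambiguous bases dropped whole). RSCU is count over synonym-family mean;
codons of unused amino acids report 0. ENC follows Wright: per amino
acid with n > 1, F̂ = (nΣp̂² − 1)/(n − 1); class means over degeneracy
2/3/4/6 use amino acids with F̂ > 0; the 3-fold class is interpolated as
(F̄₂ + F̄₄)/2 when absent; the result is clipped at 61 and reported as
missing when a required class is unavailable. CAI is the geometric mean
of relative-adaptiveness weights over the gene's codons with
single-codon amino acids excluded; weights come from an explicit
reference set via within-family count ratios with 0.5-count smoothing
for absent codons (the pipeline's default reference is the analyzed
family itself — there is no external reference set for a synthetic
genome — and any user table can be supplied instead). CBI and Fop run
over degenerate amino acids only, with N_ran = Σ n_aa·k_opt/k; the
default optimal set is the family's pooled-RSCU > 1 codons. Third-
position composition excludes ATG and TGG. Correlations are Pearson
with pairwise-complete missing handling; zero-variance columns yield
missing entries rather than errors. Internally codons are spelled with
T; reports can render U.

## Ka/Ks (NG86)

Site counts: each codon position contributes the fraction of its three
single-nucleotide changes that are synonymous to S and the complement
to N (changes creating stops count as nonsynonymous); totals are
averaged between the two sequences. Differences: per codon pair with d
differing positions, synonymous/nonsynonymous step counts are averaged
over all d! orderings of minimal mutational pathways; pathways crossing
a stop codon are excluded with renormalization (a `count_stop_paths`
flag restores naive averaging for oracle comparisons, and a codon pair
whose pathways are all blocked is excluded and logged). Proportions
ps = Sd/S and pn = Nd/N are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 saturates (missing distance), Ks = 0
leaves the ratio undefined. The estimator is symmetric in its
arguments. Codons containing gaps or ambiguity codes are excluded
whole, never patched position-wise. Other estimators (ML codon models)
are out of scope.

Tandem clusters are maximal chains of family genes on one chromosome
with consecutive members within `max_separation` bp (default 250 kb,
measured 3'-end to next 5'-start) and at most `max_intervening`
(default 5) non-family genes between them; both knobs are configurable
since no universal definition exists.

## Promoter scanning

Promoters are strand-aware upstream windows anchored at the gene
feature's 5' end (the gene models here have no UTRs, so transcription
and translation starts coincide; the anchor choice is documented rather
than guessed), default 2000 bp, truncated at chromosome edges with a
flag. The scanner expands IUPAC consensi to regular expressions with a
lookahead so overlapping occurrences all count, scans both strands,
reports forward coordinates and deduplicates palindromic double-hits by
(element, start, end). The shipped dictionary holds standard published
consensi for light/hormone/stress/flavonoid elements and is fully
user-replaceable; parity with any external promoter database is not
claimed.

## Expression quantification

ΔCt = mean target Ct − mean reference Ct per (gene, sample), replicates
averaged on the Ct scale (a `per_replicate` option computes
per-replicate folds with mean ± SE instead, matching how error bars are
usually drawn); ΔΔCt subtracts the calibrator sample's ΔCt and
fold = 2^(−ΔΔCt), so the calibrator is exactly 1. No amplification-
efficiency correction is applied. Anthocyanin units are
U = (OD530 − OD600)/gFW; negative values are returned but flagged as
blank-subtraction artifacts. Group comparison uses one-way ANOVA and
Tukey HSD (Tukey–Kramer when unbalanced) from scipy — the studentized-
range evaluation there is accurate far beyond the 1e−6 needed — with a
greedy compact letter display built from the largest mean downward
(groups sharing a letter are not significantly different; a final sweep
guarantees every non-significant pair shares a letter).

## Synthetic data: what it emulates and what it does not

The generator plants, per gene: an optional SP (M + 10 hydrophobic + 4
polar residues), one or two 54-residue PLCD blocks with ligand spacings
H·40·C·5·H·5·Z and a scaffold Cys 10 before the ligand Cys (Z = M for
UCL/PLCL, Q for SCL, a small residue for ENODL's incomplete site), an
optional 30-residue ALR at ≥ 60% P/A/S/T, and an optional 25-residue GAS
with the omega residue 22 from the C-terminus. Linkers and padding use
hydrophilic filler free of H/C/M/Q, P/A/S/T and hydrophobic runs, so
planted domains are the only detector targets. CDSs are
reverse-translated with probability mass `codon_bias_strength` on one
designated codon per amino acid (remainder uniform over the other
synonyms), giving a tunable ENC/CAI gradient. Promoter backgrounds are
scrubbed of every incidental dictionary hit before the configured
elements are inserted at recorded non-overlapping positions; junction
artifacts are re-randomized until the scan equals the expected hit set.
Because some consensi contain or reverse-complement others (a planted
G-box CACGTG necessarily contains ABRE hits; TGACG implies as-1 and a
reverse-strand CGTCA), the truth table stores both the planted positions
and the full deterministic expected counts. Duplicate pairs get exact
numbers of verified synonymous changes (anywhere) and nonsynonymous
changes (restricted to linker codons, never creating H/C/M/Q or P/A/S/T)
so the domain truth of the duplicate remains valid. Genes sit on
chromosomes inside 3 kb pads with 20–35 kb intergenic spacers, except a
duplicate which follows its partner directly (~8 kb), making tandem
pairs positionally identifiable. All randomness flows from one seed
through named per-gene streams.

Defaults mirror the family survey's study conditions: 59 genes on 12
chromosomes, subfamily mix ENODL/SCL/UCL/PLCL = 33/13/9/4, a type mix
satisfying the published architecture constraints (type II dominant,
50/59 with SP, 42/59 with GAS), codon bias 0.55, a mixed
light/hormone/stress promoter load, three purifying-regime duplicate
pairs, qPCR with six DAF stages, three replicates, reference Ct 20 and
0.2-cycle noise. Deterministic label apportionment (largest remainder)
makes small-sample mixes exact.

What the generator does **not** emulate — and hence what green tests do
not show about real data: introns and UTRs, indels and alignment
uncertainty, compositional heterogeneity inside domains (real ALRs are
not cleanly PAST-rich on a PAST-free background, so real heuristic
recovery would be far below the ~100% seen here), hydrophobic patches
outside SP/GAS (synthetic proteins are uniformly hydrophilic by GRAVY),
overlapping or nested cis-elements beyond the dictionary's own
cross-matches, amplification-efficiency drift in qPCR, and interspecies
synteny.

## Numerical choices and degenerate inputs

Bisection tolerance 1e−4 on charge (≪ 0.01 pH); ENC missing-class and
clip rules as above; CAI zero-weight errors instruct the smoothing
option instead of silently patching; `X` residues are allowed only on
request and excluded from every index; empty promoters, single-residue
instability inputs, non-positive masses, Ct values outside (0, 45) and
fold changes ≤ 0 raise immediately. Problem sizes in the test and
acceptance runs (500-gene recovery, 1000 oracle pairs, 200 scanned
promoters, 60-gene end-to-end runs) were chosen so the full suite
completes in about a minute while keeping every estimate's Monte-Carlo
error well inside its assertion margin.

## Known limitations

Heuristic detector scores are not calibrated probabilities; NG86 is a
counting estimator and will underestimate divergence at saturation; the
compact-letter-display is greedy and may use more letters than the
minimal covering; the pipeline holds genomes in memory (fine for gene
sets, not whole plant genomes); and the shipped cis-element dictionary
is a pragmatic default, not a curated database.
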