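# Methods

## Model overview

`interolog3d` transfers a known physical interaction to other species by
scoring candidate protein pairs on the interface of a solved heterodimer
(the template).  The method assumes that (a) interacting domains diverge
slowly enough that >30 %-identity homologs covering the interface retain the
binding mode, (b) interface residue preferences are captured by pairwise
contact statistics (no explicit physics), and (c) within one species, the
true ortholog pair outranks out-paralog pairs produced by pre-speciation
duplications — which is what the per-species top-rank cut exploits.

## Template extraction

PDB-format dimers are parsed to heavy atoms only; alternate locations
resolve to the highest-occupancy conformer (ties: first listed), insertion
codes are collapsed in order of appearance so template positions are 1-based
indices into the extracted chain sequence, and MSE-type modified residues
map to their standard parents (unmapped residues are excluded from contact
scoring and logged).  A contact pair is any inter-chain residue pair with a
heavy-atom distance ≤ 4.5 Å.  Interaction classes are assigned per
contributing atom pair, with sidechain = any heavy atom outside {N, CA, C,
O, OXT} (CB is sidechain; glycine contributes only backbone classes).  Pairs
touching only through backbone–backbone atoms are retained for CP counting
(the 4.5 Å rule is any-heavy-atom) but carry an internal `bb` class the
scoring matrices ignore.

Special bonds use standard structural-biology geometry, configurable because
the defining thresholds are a modelling choice: disulfide Cys SG–SG ≤ 2.5 Å;
salt bridge charged-N (Arg NE/NH1/NH2, Lys NZ, His ND1/NE2) to charged-O
(Asp OD1/OD2, Glu OE1/OE2) ≤ 4.0 Å; hydrogen bond any N/O–N/O pair ≤ 3.5 Å;
precedence disulfide > salt bridge > hydrogen bond.

A template enters the library only if both chains have ≥ 30 residues, both
interface sides have ≥ 5 contact residues and CP > 25 (strict).  Duplicates
(> 98 % global identity on both chains) are clustered transitively; each
cluster keeps the largest-CP member, ties broken by template id.

## Contact scoring matrices

Counts of residue pairs at interfaces are accumulated per class:
sidechain–sidechain counts are symmetrised (an i–j contact increments both
ordered cells), sidechain–backbone counts are directional with the
sidechain residue on rows, and special-bond tables are incremented only for
pairs forming a special bond in the template.  Each matrix cell is

    S_ij = ln(q_ij / e_ij),   e_ij = p_i · p_j

with q the (pseudocounted) observed pair probability over ordered cells and
p the row/column marginals of q.  Natural log is used throughout; the scale
cancels nowhere, so all E_vdw/E_SF values are in the same nat-scaled units.
Expected probabilities use **interface marginals** of the same count table
rather than whole-chain composition — the interface is the reference state
the odds should be taken against; this choice is flagged as open.  Van der
Waals classes use a +0.5 pseudocount per cell; special classes use raw
counts and reset never-observed cells to 0 after derivation, so chemically
impossible bonds (e.g. a salt bridge to leucine) score exactly zero.  A
class with no observations at all yields an all-zero matrix.

On any library with realistic interface composition the derived ss-vdW
matrix shows the expected hydrophobic signature (aliphatic–aliphatic block
above nonpolar–polar cells); this is asserted qualitatively, not
cell-by-cell, since matrix values depend on the training library.

## Profiles and alignment

Chain profiles are PSSMs on the BLOSUM62 half-bit scale.  In-house
construction from a star-format MSA (template first) uses Henikoff
position-based sequence weights and BLOSUM-mixture pseudocounts
f′ = (αf + βg)/(α + β), with g the BLOSUM62-conditional expectation of the
column frequencies, α = mean distinct residue types per column − 1 and
β = 10; scores are M = (2/ln2)·ln(f′/p) against Robinson–Robinson
backgrounds, so a single-sequence MSA degenerates to approximately rescaled
BLOSUM62 rows.  PSI-BLAST ASCII PSSMs can be imported instead and their
integer scores are preserved exactly.

Candidates are aligned to a profile with full Smith–Waterman/Gotoh dynamic
programming (no heuristic seeding; fine at desk scale).  Gap penalties are
the BLAST defaults 11/1, calibrated by the half-bit score scale.  Traceback
is deterministic (highest-scoring end cell, ties diagonal > up > left).
Identity is computed over aligned (non-gap) columns — the denominator is not
stated in the source description, and aligned columns is the common BLAST
convention.  Homolog families are gathered with Karlin–Altschul E-values
(gapped BLOSUM62 constants λ = 0.267, K = 0.041) at E ≤ 1e-10; this is an
in-house approximation to a BLASTP search, configurable.

## Candidate scoring and the null model

The four terms are computed on the template's contact topology with all
matrix and profile lookups at the **candidate** residues aligned to each
contact pair; a gapped position contributes zero to its term (never an
error — CR already bounds coverage).  E_sim and E_cons normalise each pair
by the BLOSUM62 diagonal of the template residues, so a self-aligned
template scores exactly 1 per pair (E_sim = CP).  Because the original
equation bodies survive only as symbol legends, this per-pair
diagonal-normalised sum is a reconstruction; a 1/CP-averaged variant sits
behind `average_sim_cons`.  E_tot = E_vdw + E_SF + E_sim + w·E_cons holds
exactly by construction; w defaults to 3.

The null model draws, per sample, ⌈0.6 · (total contact residues)⌉ positions
uniformly without replacement from the pooled interface (both chains — the
pooling is a design choice; per-chain mutation is not supported) and
replaces each with a residue ≠ wild type drawn from the interface background
frequencies.  Each randomized interface is scored as a candidate with the
full E_tot (all four terms).  Mean and sample sd (ddof = 1) over n samples
(default 10,000) define Z = (E_tot − mean)/sd; a zero-variance template is a
flagged degenerate-model error.  A single seeded generator drives each null
model and the seed is recorded in the output, so results are bit-exactly
reproducible.

## Acceptance cascade and evaluation

Candidates are same-species cross pairs of the two homolog families,
filtered by identity > 0.30 and CR > 0.5 (both strict, both chains).  Within
each (template, species) partition they are ranked by Z descending (ties:
E_tot, then id pair — "top 25 with ties" is resolved deterministically);
ranking by E_tot instead is a config switch, as the rank key is not named in
the source description.  Acceptance is Z ≥ 3.0 (≥, with a strict-inequality
switch) and rank ≤ 25.  For evaluation, pairs with a CC-RSS GO-similarity
below 0.4 are negatives, pairs on a supplied gold-standard list are
positives, everything else is unknown and excluded from the precision
denominator; recall divides by the total positives.  Threshold sweeps emit
precision/recall tables with nested acceptance sets.

## Interface evolution reports

Per species, the accepted pair with the highest Z is projected onto the
template chains (star alignment with the template as center; candidate
insertions are dropped and logged, so columns are exactly the template
positions).  A contact position is *conserved* when ≥ 70 % of non-gap rows
carry the template residue — identity to the template, not column majority,
since the report is anchored on the template structure; the threshold is a
config default because "conserved" is not quantified in the source.  It is
an *hbond* position when it participates in a hydrogen-bonded or
salt-bridged template pair.  Residues are classed into 7 physicochemical
groups (polar positive HRK, polar negative DE, polar neutral STNQ, Cys,
aliphatic AVLIM, aromatic FYW, others GP); group-level co-variation is
reported as a per-column group-composition table rather than a statistic.

## Synthetic data: what it emulates and what it does not

The toy-dimer generator places residues on a lattice (8 Å column spacing,
backbone and one representative sidechain atom per residue) so the planned
contacts are provably the only heavy-atom pairs within 4.5 Å and planted
special bonds have compliant geometry (S–S 2.05 Å, N–O 3.0 Å, O–O ≤ 3.4 Å).
Contacts are one-to-one residue pairs; defaults (26 contacts, 40-residue
chains) sit just above the library thresholds.  Homolog families mutate a
template chain to a target identity (realised within ±0.03) with
BLOSUM62-conditional substitutions, optionally sparing or targeting contact
positions and holding planned couple-conserved positions fixed; a uniform
substitution mode produces disruptive decoy interfaces.  The synthetic
alanine-scan table adds Gaussian noise to the model's own residue
contributions.

These fixtures exercise every code path deterministically, but they are not
real proteins: no packing, no rotamers, no correlated conservation beyond
the plan, chains far shorter than real domains, and the alanine-scan signal
is by construction the model's own — so the r > 0.9 recovery demonstrates
parameter recovery through noise, not agreement with experimental ddG, which
requires external alanine-scanning data.

## Problem sizes and numerical choices

Tests and the acceptance script use desk-scale sizes chosen to exercise the
statistics without waste: null models of 200–400 samples (the 10,000-sample
default is for production runs), 100 random dimers for the contact oracle,
100 planted-signal pipeline replicates, 50-residue alanine scans, ≤ 30 aa
sequences for exhaustive alignment oracles.  Ties everywhere break
deterministically (documented sort keys); degenerate inputs (empty
libraries, all-gap columns, zero-variance nulls, empty contact sets) raise
typed errors rather than propagating NaNs.  Scores are float64 throughout;
the only exact-equality assertions are identities that hold by construction.

## Known limitations

No mmCIF input, biological-assembly reconstruction or domain assignment
(the template is the whole chain interface); no iterated profile refinement;
E-value screening approximates BLASTP; cross-species candidate pairs are out
of scope; GO RSS scores are consumed, never computed.  Published large-scale
figures (genome-wide precision/recall, experimental ddG correlations) depend
on external databases and are not reproduced by the desk-scale suite.
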