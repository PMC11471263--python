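# Methods

This note documents the models and procedures fabkit implements, the
defaults that matter, and what the synthetic fixtures do and do not show.

## Domain detection and numbering

Detection is a greedy non-overlapping decomposition: the query is locally
aligned (Smith–Waterman) against every reference allele; the single best
hit — ranked by alignment score, then percent identity, then allele id —
is accepted, its span masked, and the flanking segments re-searched until
nothing passes the thresholds. Defaults: `min_identity` 50%,
`min_length` 50 residues. These separate true germline hits from
composition-matched noise in simulation (shuffled chains yield no hits at
identity 60) while tolerating heavy somatic mutation (10% substitution
load leaves both domains recovered at ≥85% identity); both are
configuration-exposed because no canonical values exist.

Scoring is the BLAST protein family: BLOSUM62, affine gap cost 11 + k for
a k-residue gap, `X` scored 0 against everything. Percent identity is
identical columns over the full alignment length, gap columns included.
The engine is an exact dynamic-programming aligner, not a heuristic
seeded search, so scores are deterministic and reproducible; a
BLAST-backed engine could be slotted behind the same interface.

Numbering is alignment transfer: the accepted span is globally aligned
(strict Needleman–Wunsch — free terminal gaps would let terminal
insertions displace real matches) to its allele's ungapped sequence, and
each query residue inherits the gapped alignment column of its reference
partner. Residues aligned to a reference gap become lettered insertions
(`112a`, `112b`, …, in query order); unmatched reference columns are
simply absent (deletions leave holes), keeping labels↔residues bijective.
This transfer is uniform for V and C domains. Known limitation: inside
long CDR insertions the canonical V-domain scheme numbers insertions
symmetrically outward from the loop centre; alignment transfer instead
letters them left-to-right, so labels there may differ from the canonical
convention. This is flagged, not silently reconciled.

The hinge may be present in a reference set as a detection target but is
excluded from numbering transfer (the C-domain scheme does not cover it).

## Chain- and structure-level annotation

**Species.** Per detected domain, the best local-alignment identity per
reference species is computed; the provided (depositor) species is kept
unless the best foreign species beats the best provided-species hit by
strictly more than `override_margin` (default 8 percentage points). If
the provided species has no reference hit at all, the best hit wins
unconditionally — a documented choice where behaviour is otherwise
under-specified. The margin is an absolute percentage-point difference;
the rule is monotone (raising the foreign identity can only trigger the
override, never revert it) and degenerates to "always keep" at margin ∞.

**Engineered formats.** All domains one species → `none`; V and C of a
chain from different species → `chimeric`; uniform species but with mixed
top-species evidence inside the V domain (top-2 species identities within
2 points — the signature of CDR grafting) → `humanized`, always
accompanied by a confidence note since no hard rule exists; anything else
→ `unresolved`.

**Isotype / light type.** The single C-domain hit with the highest
percent identity decides; ties break by alignment score then allele id.
The allele's gene prefix maps to the isotype (IGHG1→IgG1, … IGKC→kappa,
IGLC*→lambda); both the allele id and its gene prefix are reported, since
allele-level resolution (\*01 vs \*02) may exceed what identity can
support.

**Coverage.** Domains are re-detected on the ATOM-record sequence — the
residues that truly have coordinates — because the deposited SEQRES
overstates coverage. Any of CH2/CH3/CH4 resolved → `full`; else V with
CH1 or CL → `Fab`; else `other`. The classification is monotone under
adding resolved domains. Per-domain fractional coverage is resolved
residues over the reference's ungapped length.

## Geometry

**Contact matrices** are Cα–Cα distances for all label pairs of two
numbered domains; unresolved positions are NaN (never silently zero) and
can never be contacts. Default contact cutoff 8.0 Å — the common
contact-map convention, exposed because no canonical value exists for
this application.

**Packing angles.** Shared numbering labels give the residue
correspondence for a Kabsch least-squares superposition. The rotation
axis of the VL→VH superposition is the V module's pseudo-twofold; the
CL→CH1 axis is the C module's. The elbow angle is the angle between
these axes, folded into [0°, 180°] (the axes carry a sign convention —
rotation angle in (0°, 180°] — so the fold ambiguity is intrinsic); the
CH1–CL packing angle is the CL→CH1 rotation angle itself. A
`literature` convention flag unfolds elbow values below 90° to 360°−θ,
matching the (90°, 270°) range the quantity is commonly reported in.
Degenerate cases raise: fewer than 3 shared labelled Cα, collinear point
sets, and pure translations (rotation angle 0, axis undefined). On
noise-free constructed geometry recovery is exact to <1e-6°; under 0.1 Å
Gaussian coordinate noise, domain-sized correspondences (~95 points)
keep the error below 0.5°. All geometric outputs are invariant under
rigid motion of the whole assembly.

**SASA and interfaces.** Shrake–Rupley sphere sampling, probe 1.4 Å, 960
deterministic points per atom, van-der-Waals radii C 1.70 / N 1.55 /
O 1.52 / S 1.80 Å (unknown elements warn and use 1.70). Exactly
coincident equal-radius atoms are collapsed onto one sphere — the
coincident limit of two approaching atoms. A residue is interfacial when
its SASA drops by more than `delta_sasa_threshold` (default 1.0 Å², the
conventional per-residue noise floor) between the isolated chain and the
two-chain complex; buried area is the summed loss over both chains
halved. When several heavy and light chains are present, H–L pairing is
by descending buried interface area.

**Disulfides.** Cysteine pairs with Sγ–Sγ distance ≤ 2.5 Å, tagged intra-
or inter-chain.

## Search

The index stores, per H–L pair, V-only and V+C sequence views of each
chain (from the numbered domains) and optionally the CH1–CL contact
matrix. Sequence search locally aligns each present query chain against
the matching view of every entry; a paired query's combined identity is
the unweighted mean of its chain identities (no principled weighting
exists; a weight option is exposed through per-chain identities in the
results). Repertoire input dialects: FASTA (unpaired), AIRR-style TSV and
CSV (rows paired by `cell_id`, loci IGH vs IGK/IGL; column mapping
overridable; nucleotide-only files are rejected, translation is out of
scope), and 10x-style contig CSV (paired by barcode). Batches over 200
records are refused unless `no_limit`, mirroring the batch limit of the
interactive service this mirrors.

Interface similarity restricts both contact matrices to their shared
label support and takes the Jaccard index of the contact sets (empty
shared union counts as identical; no shared labels scores 0 with a
warning). A distance-correlation alternative (`method="distance"`,
Pearson r on shared distances clipped to [0,1]) is provided because the
canonical metric for this comparison is not fixed.

## Mutational-scan post-processing

Score tables are long-form CSV (`position_label, wt_aa, mut_aa, score`)
pivoted to position × 20 matrices; missing values stay explicit (NaN).
WT-relative scaling subtracts each position's wild-type score, making WT
cells exactly 0 and every other cell a preference change versus WT.
Multi-mutant scores are sums of scaled single-mutation scores — valid
only under the independence assumption (no compensatory coupling), which
is echoed in the output, and only for scorers whose scores are additive:
energy-based point-scan tables (`rosetta_pmut` tag) are computed per
mutation in isolation and are refused unless forced.

**Isotype sensitivity.** Given scans of the same V region in the context
of isotype A, isotype B, and a second isotype-B structure (the
within-isotype control), per position p over the ≤19 non-WT substitutions:
`d_iso = score_A − score_B`, `d_ctrl = score_C − score_B`. The default
effect is a signed log2 fold difference of comparison magnitudes,

    effect(p) = sign(mean d_iso) · log2((mean|d_iso| + ε) / (mean|d_ctrl| + ε)),

ε = 1e-6, negative meaning the first isotype is favoured. The design was
genuinely open here; an alternative that ratios the absolute *means*
rather than the mean *absolute* differences (`effect_method="mean"`) is
implemented but not the default, because a near-zero mean of the control
differences — which happens by chance at null positions — inflates its
fold ratio arbitrarily, drowning genuine signal; the mean-absolute form
recovers planted shifts reliably (3/3 planted positions top-ranked in
every simulation tried) while agreeing on sign. Significance is a
two-sided Wilcoxon signed-rank test of d_iso against d_ctrl (≤19 pairs;
no normality assumption; all-zero differences give p = 1), corrected
across positions by Benjamini–Hochberg. Positions with fewer than two
substitutions scored in all three matrices are skipped with a note.
Under three i.i.d. noise scans the raw p < 0.05 fraction sits near the
nominal level (0.02–0.09 across seeds at 200 positions).

## Synthetic fixtures

The generators produce, from one integer seed, byte-identical text files:

- **Reference sets**: per species one allele per domain (default two
  species, ~580 ungapped C+V residues each). Species 0 carries the
  ancestral sequences; others are substituted at rate `divergence`
  (default 0.15, i.e. homologs ~85% identical — a plausible
  between-mammal germline distance and comfortably beyond the 8-point
  override margin). Gap columns are fixed per numbering scheme; CH1 and
  CL share one scheme (as all V domains do), which is precisely what
  makes cross-domain label correspondence — and hence packing-angle and
  interface comparison — possible.
- **Structures**: Cα-trace idealisations. Each domain is a compact
  helical curve; VL is a rigid copy of VH rotated by a planted dyad
  angle, CL a rigid copy of CH1 rotated about an axis tilted from the V
  axis by exactly the requested elbow angle. Planted disulfides are Sγ
  pairs at 2.05 Å; unresolved spans are omitted from ATOM records but
  kept in the polymer sequence. Ground truth (angles, brute-force CH1×CL
  contacts, disulfides, coverage class) is written to a JSON sidecar, and
  tests read truth only from the sidecar.
- **Repertoires**: paired H/L chains derived from the references with a
  5% default per-residue mutation load (a heavy somatic-hypermutation
  burden), some cells left unpaired; identical logical content across
  dialects.
- **Scores**: Gaussian noise (σ 0.5) with a +2.0 shift planted at 3 of 50
  positions in one pseudo-isotype — an unambiguous 4σ per-substitution
  signal appropriate for verifying recovery machinery.

What passing these fixtures does **not** show: the structures are not
physically realistic folds (no secondary-structure packing, no side
chains beyond planted Sγ), the reference sets are not real germline
nomenclature, and score noise is i.i.d. Gaussian whereas real scan scores
are position-correlated. The fixtures validate the *machinery* — exact
numbering transfer, rule application, geometric recovery, statistical
calibration — not biological conclusions.

## Numerical and determinism notes

- All randomness flows through `numpy.random.default_rng(seed)`; fixture
  files fix float formatting (3 decimals in mmCIF) for byte determinism.
- Alignment ties break deterministically (score, then identity, then
  allele id); altloc ties break by occupancy then alphabetically; search
  ties by entry id. Pipeline output is sorted by entry and chain, so CSV
  bytes are independent of input order, and every output carries a
  comment header echoing the configuration and tool version.
- Per-entry failures in batch runs are isolated and logged rather than
  aborting the batch; the exit status reflects whether any entry failed.
- Problem sizes in the test-suite simulations (50 alignment pairs,
  95-residue domains, 20 rigid motions, 50 noise trials, 200-position
  null scans, 20-entry retrieval databases) were chosen as the smallest
  sizes at which the checked statistics are stable.
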