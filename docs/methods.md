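# Methods

This note records the models implemented in `tmsid`, the parameter choices
that matter, the design decisions taken where the design was genuinely
open, and what the synthetic benchmark does and does not demonstrate.

## Spectra and curation

A spectrum is a peak list (m/z, abundance) at nominal (unit) resolution
with identity metadata. Abundances are instrument-arbitrary; duplicate m/z
within a record merge by intensity sum (abundances are ion counts).

Training-library curation runs in a fixed order — structural triage,
high-mass cut, spectral quality, m/z clamp — and every removed record
names exactly one rule (first match wins), so
`n_input = n_output + Σ removals` holds identically. Choices worth
flagging:

* **Structural triage is rule-based, not manual.** Each of the thirteen
  exclusion categories is an explicit matcher (SMARTS patterns plus
  procedural bond checks); `tmsid.fingerprints.export_pattern_files` and
  the category list in `curation.py` make the rules auditable. "C–Si
  bonds" means C–Si *outside* intact TMS/TBDMS groups — every silyl group
  contains C–Si, so the literal reading would exclude everything. A silyl
  silicon whose fourth substituent is carbon is not a derivatization
  product and counts as a stray C–Si bond.
* **High-mass cut** defaults to strictly `M_w > 1000` Da;
  `>=` is available (`mass_mode`). Records without a known M_w go to a
  needs-review bucket rather than being silently kept.
* **Quality criteria** use ±0.5 Da tolerances (unit-resolution quadrupole
  data). The molecular ion is located at the rounded exact mass when an
  exact mass is present, else at the rounded average M_w. The
  acquisition-range criterion is a property of the scan window, which a
  peak list does not carry: an `AcqMzMax` metadata field is honoured when
  present; otherwise the maximum observed peak m/z serves as a proxy. The
  TMS-marker criterion accepts any one of m/z 73/147/221/295 by default; a
  strict mode demands the marker matching min(n_TMS, 4).
* **m/z clamp** is a closed interval [50, M_w + 10], applied last, and
  idempotent.

## Spectral similarity

Binning uses half-open 1.0 Da bins, index = floor(m/z / width), with the
bin value the *mean* intensity of the peaks it contains. Cosine
similarity of two binned vectors is exactly 1 for identical inputs
(short-circuited before the floating-point dot product) and 0 for
disjoint support; two all-zero vectors raise rather than return a silent
0. Consensus spectra average the max-normalized member vectors, so
high-abundance acquisitions do not dominate. Clustering is hierarchical
agglomerative (average linkage) on 1 − cosine with a user-supplied
cluster count. The conventional reproducibility threshold (cosine 0.50)
is surfaced as a QC flag only; flagged replicates stay in the dataset.

## Fingerprints

Structures are stripped of stereochemistry (EI spectra do not distinguish
stereoisomers). Four binary families concatenate in fixed order to 6,214
bits: substructure (307), MACCS (166), PubChem-style (881),
Klekota-Roth-style (4,860). The MACCS block is RDKit's implementation
with the unused padding key 0 dropped. The other three families are
synthetic stand-ins for the original CDK definitions, which are not
redistributable here: deterministic enumerations of curated
functional-group SMARTS, element/ring-count thresholds, and bonded-chain
patterns over an H-count/ring-aware atom alphabet, at exactly the
published family sizes. The contract is therefore block lengths and
behavioural properties (purity under canonicalization, masking algebra),
not bit-level parity with any CDK release.

Column masking removes bits constant over the training set and, within
each group of identical columns, all but the lowest-index member; the
mask records a per-column rule and a layout hash, and double-masking is
rejected.

## PPK and kernel processing

Peaks are modelled as 2-D Gaussians with shared diagonal covariance
diag(σ_m², σ_I²); a spectrum is the uniform mixture (weight 1/N per
peak); the kernel is the closed-form integral of the mixture product.
Bandwidths are not instrument constants and are config-exposed:
σ_m = 0.5 Da (nominal-resolution EI) and σ_I = 0.05 on per-spectrum
max-normalized intensities. Gram matrices are computed by a banded sweep
over the pooled m/z-sorted peaks: pairs further apart than 14 σ_m
contribute below exp(−49) ≈ 5·10⁻²², beneath double-precision resolution
of any accumulated entry, so the banded result is exact to round-off
while turning the all-pairs cost into a near-linear one.

Kernels are centered then cosine-normalized (order config-exposed);
cross blocks are centered with the training means and normalized with
centered self-similarities, so test points live in the training feature
space. Centering is an idempotent projection and preserves positive
semi-definiteness; normalization bounds entries in [−1, 1].

## IOKR

With centered+normalized train Gram K (n×n) and masked fingerprint
matrix Y (n×p), the fitted map is h(x) = Yᵀ(K + λI)⁻¹k_x, solved through
a Cholesky factor (never an explicit inverse); a singular system raises
with a condition-number diagnostic. λ is selected on a grid
(default 10⁻⁵…10¹) by k-fold CV (default 5 folds, seeded and logged)
minimizing output-feature MSE — cheaper than a ranking objective and
adequate because the scoring step only needs relative geometry; ties go
to the smallest λ. Candidates are scored with the linear output kernel
⟨ψ(c), h(x)⟩; a cosine variant (score divided by ‖ψ(c)‖) is available
behind `normalized_scores` for candidate sets of heterogeneous size.
Ranking is descending by score with ties broken lexicographically by
identifier (determinism over arbitrariness); exact score ties — which
arise from identical fingerprints — are recorded as tie groups. A query
whose candidate set lacks the truth is "missing".

## Evaluation

ARP counts candidates *strictly* better than the truth, plus one (tied
candidates are not "better"). RRP = ½(1 + (BC − WC)/(TC − 1)) is 0 at
rank-first, 1 at rank-last, and undefined at TC = 1; the convention here
is 0 (a singleton candidate set containing the truth is trivially
rank-first) and every use is counted in the summary. Missing queries
remain in the top-k denominators but are excluded from mean ARP/RRP —
the accounting that reconciles with published-style summary tables
(e.g. 39 of 104 queries in the top 10 reported as 37.5% alongside 32
missing). Summaries are produced merged and per group (in-training flag,
structural class, spectral cluster).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes;
it is not a physical fragmentation model (no rearrangement chemistry, no
isotope envelopes beyond M+1, no retention information).

* **Compounds** come from a deterministic grammar of TMS-derivatizable
  scaffolds (substituted phenols, bisphenols, aliphatic alcohols/acids,
  polyols, cyclohexanols and fused-ring alcohols, amines, amino acids,
  heteroaromatics, nitrophenols, fluorinated chains), deduplicated by
  InChIKey and filtered to M_w 182–575 Da and 1–5 TMS groups — the span
  of real derivatized test compounds. The pool holds 489 structures; six
  attachment-moiety classes double as designed cluster labels.
* **Spectra are generated from fingerprints.** The pipeline's
  learnability assumption is precisely that spectra carry fingerprint
  information, so the minimal faithful generative stand-in hashes each
  *distinctive* active bit (bits varying across the compound universe) to
  a fragment m/z; universe-constant bits describe the shared silyl
  chemistry, which the spectrum already carries as the TMS marker ions
  (73/147/221/295, added for min(n_TMS, 4)). Fragments land in
  [50, 180) Da — below the lightest molecular ion, since EI fragments
  cannot outweigh the parent — which also keeps the training library's
  m/z clamp information-neutral. Collisions (two bits, one bin) are
  allowed and create realistic ambiguity. The molecular ion and a
  carbon-count-scaled M+1 isotope peak are added; the scan-range
  metadata records 50–800 amu.
* **Noise model**: multiplicative lognormal intensity noise (default
  sd 0.05), per-fragment-component dropout (default p 0.02; structural
  peaks are exempt so compliant spectra satisfy the quality criteria by
  construction, and dropout removes one ion species of a shared bin, not
  the bin), and uniform background clutter (default 3 peaks). Fragment
  base intensities sit in [0.08, 0.30] relative to the marker base peak,
  as in real silyl-derivative EI spectra where m/z 73 dominates; with
  ~50–80 fragment components this keeps any single dropout event small
  against the spectral norm, and replicate cosines stay above the 0.95
  reproducibility level at the low-noise settings.
* **Candidate sets** draw decoys at a controlled Tanimoto similarity to
  the truth (default band [0, 0.4]), measured over the pool's
  *informative* fingerprint columns — in a universe where every member
  carries the same silyl scaffolding bits, whole-vector Tanimoto has a
  high floor and the low band would be geometrically empty. An optional
  `p_missing` removes the truth from a fraction of sets.
* **Determinism**: every artifact derives from `master_seed`; the
  deterministic spectrum core (fragment map, markers, molecular-ion
  cluster) is seed-independent, so zero-noise spectra are bit-identical
  across seeds.

What passing the benchmark shows — and does not. The reference
conditions (300 training compounds, 50 queries with 60% also in
training, 50 candidates per query, low noise) give top-1 ≈ 100% and mean
RRP ≈ 0, degrading monotonically to ≈ 24% top-1 as noise, dropout and
decoy similarity rise. This demonstrates that the pipeline recovers
structure when spectra carry fingerprint signal and that its difficulty
knobs behave; it says nothing about accuracy on real EI spectra, whose
fragment–substructure relationship is far noisier than the generator's
hash map. Published evaluations on curated reference libraries report
top-10 accuracies nearer 40%.

## Numerical conventions and degenerate inputs

* Cosine of two all-zero vectors, PPK of an empty spectrum, ranking an
  empty candidate set, and top-k of an empty result list raise; they are
  contract violations, not zeros.
* `cosine(v, v)` returns exactly 1.0; matrix diagonals are pinned to 1.
* The m/z clamp and kernel centering are idempotent; re-masking a masked
  fingerprint and non-positive self-similarities raise.
* CV fold assignment uses `numpy.random.default_rng(seed)`; all λ ties,
  score ties and duplicate-column choices resolve to the lowest
  index/identifier.
* Problem sizes in the test suite (60–300 training spectra, 10–50
  queries, 15 replicates, 40-compound reproducibility panels) were chosen
  to exercise every code path at desk scale.

## Known limitations

* The three in-house fingerprint families are not CDK's; masks and models
  built with other fingerprint software are not interchangeable with
  `tmsid`'s.
* Candidate retrieval is file-based; there is no live compound-database
  query. Molecular formulas of queries are assumed known.
* The PPK bandwidth defaults suit unit-resolution EI data; high-resolution
  spectra need σ_m re-tuned.
* Curation's rearrangement-TMS rule only recognizes enol-type O-TMS on
  non-aromatic sp² carbons; exotic rearrangement products pass.
* Eq.-style RRP is undefined for singleton candidate sets; the 0
  convention is flagged in summaries (`singleton_rrp_used`).
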