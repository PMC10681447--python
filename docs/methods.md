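# Methods

## The screening model

The screen encodes one structural hypothesis: peptides that inhibit
α-synuclein pathogenic aggregation do so by presenting a hydrophobic face
and a cationic face on the same α-helix. The cationic face carries the
peptide through the anionic fuzzy coat of toxic oligomers and fibrils; the
hydrophobic face then engages the exposed aggregation-prone clusters. The
four criteria (helicity, amphipathicity, cationicity, helix-compatible
length) are each a necessary condition for that mechanism, and the decision
is their conjunction. The screen is a heuristic triage, not a binding-energy
model: it makes no claim about affinity or kinetics, only about whether the
architecture is present.

## Amphipathicity: the hydrophobic dipole moment

For residues n = 0…N−1 with hydrophobicities Hₙ placed at successive 100°
rotations, the per-residue moment is

    uH = (1/N) · sqrt[ (Σ Hₙ sin δn)² + (Σ Hₙ cos δn)² ],  δ = 100°.

`hydrophobic_moment` implements exactly this. The *screening statistic*
(`mean_windowed_moment`) evaluates it on every 18-residue window and
averages; sequences of ≤ 18 residues use the single full window. The window
equals the minimum helix length of the decision rule: a long peptide is
amphipathic if its helix-sized stretches are, and a single global moment
would otherwise dilute (or, with max-pooling, overstate) face segregation.
The windowed mean with the Fauchère–Pliska octanol/water scale reproduces
the reference amphipathicity values of all four case-study peptides to
±0.02 (three of four at 2-decimal printing precision), which is the
calibration standard this default was selected against; the Eisenberg
consensus scale is bundled as an alternative and any 20-residue scale can be
supplied as a key-value file. δ is configurable but defaults to the ideal
α-helix value.

## Charges: Henderson–Hasselbalch at a chosen pH

Each ionizable group contributes a fractional charge

    basic  (H, K, R, N-term):  +1 / (1 + 10^(pH − pKa))
    acidic (D, E, C, Y, C-term): −1 / (1 + 10^(pKa − pH))

with textbook pKa defaults (D 3.65, E 4.25, C 8.30, Y 10.07, H 6.00,
K 10.53, R 12.48, N-term 9.00, C-term 3.10), all user-overridable. Free
termini contribute charge by default; acetylation/amidation flags zero the
corresponding terminus. NCPR divides the summed net charge by the residue
count (terminal groups add charge, not length). Histidine is basic with
fractional protonation (≈ 0.09 at pH 7), never ignored.

The cationicity criterion counts residues whose fractional charge exceeds
+0.5 — i.e. predominantly protonated basic side chains at the working pH —
and requires one per 18 residues. This literal residue-count reading, rather
than a threshold on fractional NCPR, is what admits weakly-but-definitely
cationic case-study regions (e.g. two basic residues in a 20-mer whose NCPR
is only +0.05); NCPR itself is still computed and reported for every
sequence. No ionic-strength or temperature corrections to pKa are applied.

## Helicity: a Lifson–Roig helix–coil model

AGADIR-style percent helicity of a monomeric peptide is estimated with a
single-sequence Lifson–Roig model. Each residue is helical (h) or coil (c);
a state sequence has weight ∏ᵢ tᵢ with tᵢ = wᵢ when residue i is h with h on
both sides, tᵢ = v when h otherwise, tᵢ = 1 when c. Mean helicity is the
average probability of the w-state (being inside a segment of ≥ 3
consecutive h residues), in percent. The partition function and per-residue
probabilities are computed with 4×4 transfer matrices over (prevState,
curState) pairs and a forward–backward pass, O(N) per sequence; peptides of
1–2 residues score exactly 0.

Parameters, with defaults and provenance:

- **w (propagation)**: per-residue, from a published experimental
  helix-propensity table of ΔΔG values relative to alanine, anchored at
  w(Ala) = 1.61 at the 278 K reference temperature:
  wᵢ(278) = 1.61 · exp(−ΔΔGᵢ / RT). Proline (ΔΔG 3.16 kcal/mol) is
  effectively a breaker.
- **v (nucleation)**: 0.036, residue-independent, the standard Lifson–Roig
  value.
- **Temperature** (kelvin, default 278): van 't Hoff dependence with helix
  formation enthalpy ΔH = −0.9 kcal/mol per residue, so every wᵢ — and hence
  the score — decreases monotonically with temperature.
- **Terminal penalty**: a free (charged) terminus destabilises a terminal
  helical residue by 0.5 kcal/mol; acetylation/amidation removes the
  corresponding factor. This gives the expected protection-raises-helicity
  behaviour.
- **pH and ionic strength** are accepted in `HelicityConfig` for interface
  fidelity with external predictors but are ignored by the built-in model
  (no electrostatics); this is a documented limitation, not an oversight.

`enumerate_helix_content` is the independent oracle: an explicit sum over
all 2^N state assignments, limited to N ≤ 14; the transfer-matrix engine
must (and does, in the tests) agree with it to 10⁻⁹.

The built-in model is a transparent approximation, **not** a
reimplementation of AGADIR: it lacks capping motifs, side-chain–side-chain
interactions and electrostatic screening. Published AGADIR scores are
therefore handled by the external-score adapter (`ExternalScores`), which
maps record ids — and, for window scanning, exact sequences — to scores. In
strict mode (no fallback) the table is the sole helicity authority and
unmatched sequences score 0, reproducing a published screening decision
exactly; with the built-in model as fallback, unmatched window candidates
get model scores instead. The two modes answer different questions ("what
did the published predictor decide" vs "what does my best estimate decide")
and the CLI exposes both (`--external-scores` ± `--external-only`). With the
built-in estimator alone, window-level scores differ from AGADIR's and a
region search may return a different (typically longer) passing stretch
than a published AGADIR-based run — observed for the neuropeptide-Y case,
where only the strict adapter path pins the region to 16–36.

## Region search

`find_region` evaluates **all** substrings with length in
[len_min, min(L, len_max)], longest first, most N-terminal first, returning
the first pass. This subsumes the nominal "18-residue sliding window": the
detected regions of interest are frequently longer than 18 (21, 38, 20 in
the case studies), which only a full length-range scan can return while
still honouring "the longest positive stretch is reported". Substring
helicity is computed on the isolated substring; protection flags are
inherited only where the substring reaches the corresponding end of the
parent. Full-length peptides longer than len_max are never positive as a
whole and go directly to region search. The exhaustive-substring oracle in
the tests re-derives the longest passing substring independently and must
agree on every random sequence tried.

## Synthetic benchmark generator

`synthetic` builds labeled fixtures from the wheel geometry itself.
Positives: positions whose wheel angle falls within ±80° of the reference
direction get hydrophobic residues (Leu-weighted with Ile/Phe); the opposite
face gets K/R (probability 0.6) or Ala. Leucine and alanine dominate because
they are strong helix propagators, making the construction satisfy the
helicity criterion through the same model the screen uses, not by fiat. The
generator then *verifies* its guarantees (uH ≥ 0.4, NCPR ≥ 0.1) with the
package's own calculators, redrawing deterministically on failure.

Negative kinds each break one named criterion: `short` (< 18 residues),
`acidic` (D/E face, NCPR < 0 verified), `scrambled` (permutation of a
positive, re-drawn until **every** 18-residue window has uH < 0.2 — which
bounds the windowed-mean moment of every admissible substring below
threshold, so the region search cannot resurrect the peptide), and `low_uh`
(strict hydrophobic/charged alternation, same all-window check). All
randomness flows from per-record seeds derived from the dataset seed;
identical specs give byte-identical datasets.

What the generator does **not** emulate: real amino-acid composition
statistics, homology structure, post-translational modifications, or any
actual aggregation-inhibition activity. Recovery of generator labels
demonstrates internal consistency of screen + generator on clean
archetypes; it says nothing about sensitivity/specificity on real peptide
databases.

## Numerical and interface choices

- Coordinates are 1-based inclusive everywhere a region is reported.
- Results tables are TSV (sequences never need quoting), floats at 2
  decimals; re-parsing a table recovers the producing values at that
  precision.
- Deduplication keys on the exact sequence string, first occurrence wins;
  how duplicates with differing terminal modifications should merge is
  genuinely underdetermined, so the flags of later duplicates are dropped
  and the removed count is reported.
- Region ties (equal length) resolve to the smallest start index — a
  deterministic rule chosen because the N-terminal-most stretch is reported
  first in the conventions this tool follows.
- The Lifson–Roig partition function is computed in double precision without
  log-space rescaling; weights stay well within range for peptides up to
  several hundred residues, far beyond the 54-residue screening ceiling.
- Screening is O(L²) substring evaluations per negative peptide, each O(L):
  a 3 500-peptide batch of ~30-mers (the advertised single-job size) runs in
  a few minutes on one CPU; the bundled test suites use hundreds of
  peptides and finish in well under a minute each.

## Known limitations

- The built-in helicity model ranks helix formers sensibly but its absolute
  percentages are not AGADIR's; decisions near the helicity threshold can
  differ from AGADIR-based runs (use the adapter for published scores).
- The hydrophobicity default was calibrated against four reference values;
  other published uH figures computed with different scales/windows will not
  be matched without configuring the same scale.
- No modelling of aggregation kinetics, binding affinity, toxicity,
  permeability or expression — the screen is architecture triage only.
- Only the 20 canonical residues are supported; modified or non-natural
  peptides are flagged invalid rather than approximated.
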