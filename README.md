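# amphiscreen

Physicochemical screening of peptides for the architecture that inhibits
α-synuclein (aSyn) pathogenic aggregation.

aSyn toxic oligomers and fibrils expose hydrophobic clusters inside a highly
anionic surface. Peptides that bind them selectively — without touching
functional monomeric aSyn — share one architecture: an **amphipathic,
cationic α-helix** of helix-compatible length. `amphiscreen` implements the
heuristic decision rule that detects this architecture from sequence alone,
for triaging neuropeptides, antimicrobial peptides, food-derived bioactive
peptides or designed sequences as candidate aggregation inhibitors.

## The decision rule

A peptide is a **positive hit** when all four criteria hold:

1. **Helicity** — mean percent α-helicity ≥ 1 (user-variable; lower it to
   admit disordered peptides that may fold upon binding). Scores come either
   from the built-in Lifson–Roig helix–coil model or from an external
   predictor's output via an adapter.
2. **Amphipathicity** — hydrophobic dipole moment
   ⟨μH⟩ = (1/N)·|Σₙ Hₙ e^(iδn)| ≥ 0.2, with δ = 100°/residue and Hₙ the
   Fauchère–Pliska hydrophobicity; for peptides longer than one helix window
   (18 residues) the moment is averaged over all 18-residue windows.
3. **Cationicity** — at least one positively charged residue per 18
   residues, where "positively charged" means a Henderson–Hasselbalch
   fractional charge > +0.5 at the working pH (K and R at pH 7). The
   fractional net charge per residue (NCPR) is computed and reported.
4. **Length** — 18–54 residues (5–15 helical turns at 3.6 residues/turn).

When the full-length peptide is negative, a sliding-window search evaluates
every internal substring of admissible length and reports the **longest
passing region** (ties broken toward the N-terminus). Helical-wheel layouts
(100°/residue) visualise the hydrophobic and cationic faces. N-terminal
acetylation and C-terminal amidation can be flagged; they remove the
corresponding terminal charge and terminal helix destabilisation.

## Worked example

`python examples/screen_case_studies.py` screens four well-characterised
peptides, feeding their published helicity scores through the external-score
adapter:

```
id         decision            uH   NCPR region
NPY        positive_region   0.34  +0.00 16-DMARYYSALRHYINLITRQRY-36
BMAP28     positive_full     0.63  +0.33 -
LfcinH     positive_region   0.27  +0.18 8-QWCAVSQPEATKCFQWQRNMRKVRGPPVSCIKRDSPIQ-45
OR7_region positive_full     0.32  +0.05 -
```

The 36-residue neuropeptide Y is negative as a whole (its acidic N-terminal
half cancels the net charge) but contains a 21-residue C-terminal region,
positions 16–36, that is helical, amphipathic (μH = 0.44) and cationic — the
region search recovers exactly that stretch. BMAP-28 passes full-length with
the strongest amphipathicity of the four (μH = 0.63, NCPR = +0.33).

Other entry points:

- `examples/helicity_model.py` — the built-in helix–coil model vs its
  enumeration oracle, temperature dependence, terminal protection;
- `examples/design_synthetic_benchmark.py` — labeled synthetic positives /
  negatives generated from the wheel geometry and screened back;
- `examples/helical_wheel.py` — face segregation on the wheel projection;
- CLI: `amphiscreen screen input.fasta -o results.tsv`,
  `amphiscreen generate --out-prefix bench`, `amphiscreen wheel SEQ -o w.tsv`.

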