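# songseq

Sequence statistics and tutor–pupil comparison for Bengalese finch song.

Bengalese finch (*Lonchura striata* var. *domestica*) song is a learned
sequence of discrete syllables organized into stereotyped chunks
("motifs", 2–7 syllables) and variable nodes ("branch points": a motif
followed by several possible transitions, none produced ≥ 95% of the
time). When a juvenile (pupil) learns from an adult (tutor), it
reproduces not just syllables but the *statistics* of the tutor's
sequences — syllable prevalences, pairwise transition probabilities,
motif inventories, and branch-point transition distributions.
`songseq` provides the full analysis tool-chain for quantifying this
kind of vocal sequence learning from labelled song corpora, plus a
generative song-grammar simulator for validating the analysis end to
end against known ground truth.

## What it computes

For a corpus of song bouts (plain-text label sequences):

- **Sequence statistics** — syllable prevalence, first-order transition
  tables with explicit end-of-bout accounting, transition entropy
  `H = Σ −pᵢ log₂ pᵢ` (bits), mean repeat numbers of repeated
  syllables, and split-half reliability of transition-probability
  estimates.
- **Structure discovery** — motifs via greedy bidirectional chaining on
  the transition graph (merge `u→v` when both p(v | u) and p(u before v)
  reach a stereotypy threshold, default 0.75), and branch-point
  classification at the inclusive 95% stereotypy threshold.

For a tutor–pupil pair sharing a label space:

- **Retained / dropped / novel** classification at four levels:
  repertoire, pairwise transitions, motifs, branch points.
- **Motif edit scoring** — additions and deletions against the
  longest-common-subsequence backbone, positioned as
  beginning / middle / end of the tutor's motif (e.g. tutor `abcd` vs
  pupil `rtbcd` = one beginning deletion `a` plus beginning additions
  `r`, `t`).
- **Positional chance models** — pooled-slot expected probabilities of
  edits by position given the tutor's motif-length multiset (lengths
  {2,3,4,5} give 29/43/29% for deletions, 22/55/22% for additions), and
  a likelihood-ratio (G) goodness-of-fit test of observed edit
  positions against them.
- **Branch-point fidelity** — the total deviation in transition
  probability, `100 × Σ |p_tutor − p_pupil|` over the union of
  transitions: 0% for a perfect copy, 200% for disjoint supports.
- **Acoustic similarity without classification** — per-feature
  Bhattacharyya distances (Gaussian closed form or histogram variant)
  between pooled syllable feature distributions.

The synthetic module samples tutor grammars with realistic structure
(3–6 motifs, ~55-syllable bouts, 1–4 transitions per branch point),
derives pupils under a parameterized learning model
(prevalence-dependent retention, noisy transition copying,
position-biased motif edits, novel elements) with a ground-truth edit
log, and samples corpora from either.

## Worked example

```python
import songseq as s

tutor_g = s.sample_tutor_grammar(seed=1)
pupil_g, log = s.derive_pupil(tutor_g, seed=2)
tutor = s.sample_corpus(tutor_g, 40, seed=3, with_features=False)
pupil = s.sample_corpus(pupil_g, 40, seed=4, with_features=False)

result = s.compare_corpora(tutor, pupil)
rep = result["repertoire"]
n_tutor = len(rep.retained) + len(rep.dropped)
print(f"retained {len(rep.retained)}/{n_tutor} tutor syllable types "
      f"({rep.pct_retained_of_tutor:.1f}%)")
print(f"novel syllables in pupil: {rep.pct_novel_of_pupil:.1f}%")
for c in result["motif_comparisons"]:
    print("motif", " ".join(c.tutor_motif.labels), "->", c.status,
          f"(shared {c.shared_fraction:.2f})")
for bc in result["branch_point_comparisons"]:
    seq = " ".join(bc.tutor_bp.sequence.labels)
    if bc.status == "retained":
        print(f"branch point {seq} retained: total deviation "
              f"{bc.total_deviation_pct:.1f}%, entropy "
              f"{bc.entropy_tutor:.2f} -> {bc.entropy_pupil:.2f} bits")
    else:
        print("branch point", seq, bc.status)
for e in result["edits"]:
    print("edit:", e.type, e.label, "at", e.position,
          "of", " ".join(e.tutor_motif))
```

prints

```
retained 12/19 tutor syllable types (63.2%)
novel syllables in pupil: 0.0%
motif l m n o p q r -> dropped (shared 0.00)
motif a b c d e -> modified (shared 0.60)
motif s -> matched (shared 1.00)
motif f g h i j k -> matched (shared 1.00)
branch point l m n o p q r dropped_sequence
branch point a b c d e retained: total deviation 104.8%, entropy 1.00 -> 0.97 bits
branch point s dropped_stereotyped_in_pupil
branch point f g h i j k dropped_stereotyped_in_pupil
edit: deletion a at beginning of a b c d e
edit: deletion b at middle of a b c d e
```

The pupil kept 12 of the tutor's 19 syllable types, matched two motifs
exactly, modified one (two syllables deleted from its start), and
dropped the longest motif outright; at the one retained branch point
the pupil's transition distribution deviates from the tutor's by 105
percentage points of probability mass (out of a possible 200).

The same pipeline runs from the shell:

```sh
songseq simulate --seed 3 --n-bouts 40 --out sim/
songseq compare --tutor sim/tutor.bouts --pupil sim/pupil.bouts --out cmp/
songseq test-chance --lengths 2,3,4,5 --edit-type deletion --observed 8,12,4
```

File formats are plain text throughout: one bout per line (`.bouts`),
gap/feature CSVs keyed by bout index and position, grammar JSON, and
tidy CSV reports (see `docs/methods.md`).

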