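# dirsel

Detect **directional selection in proteins** from quantitative amino-acid
property changes.

Each inferred amino-acid replacement is scored as a signed change (*delta*)
in one physicochemical property — hydropathy, polarity, buriedness, and so
on.  For a set of replacements and one property, a two-tailed one-sample
t-test asks whether the mean delta differs from zero (H0: mu = 0, "no net
change").  A significant positive or negative mean indicates replacements
accumulating in the same physicochemical direction, i.e. directional
selection on that property.  Tests can be run per property across a
built-in panel of 25 representative scales (8 categories), and per sequence
partition (whole sequence, sliding windows, or named regions such as
functional domains).

Because the method needs only amino-acid differences — no underlying
nucleotides, no synonymous rates — it accepts aligned protein pairs and
BLAST tabular output directly, alongside coding-sequence pairs (translated
in-package with a selectable genetic code) and externally produced
replacement tables (e.g. per-branch lists from ancestral reconstruction).

## Command line

```sh
# whole-sequence panel over the 25 built-in properties, TSV output
dirsel analyze --mode protein-pair --input a.fasta --input b.fasta

# replacement table (site/from/to TSV), one property, signed-symbol grid
dirsel analyze --mode table --input reps.tsv --properties h --format grid

# coding-sequence pair, invertebrate mitochondrial code, named regions
dirsel analyze --mode cds-pair --input x.fasta --input y.fasta \
    --genetic-code 5 --partition regions --regions-file regions.tsv

# BLAST tabular input (-outfmt "6 std qseq sseq"), one report per HSP
dirsel analyze --mode blast --input hits.tsv

# inspect or export the property panel; load extra scales from AAindex files
dirsel scales list
dirsel scales export --format aaindex --out panel.aaindex
dirsel analyze --mode table --input reps.tsv --scales-file my_scales.aaindex

# seeded null / power calibration of the test
dirsel simulate --n 15 --trials 10000 --seed 1 --bias 0 --bias 1 --bias 4
```

Grid reports use a signed significance notation: `+`/`-` per tier met
(default tiers p < 0.1 / 0.05 / 0.01), so `---` means a decrease significant
at all three tiers.  TSV/JSON reports carry the full statistics (n, mean,
sd, se, t, df, p, net change) per property and partition.  `--adjust` adds
a Benjamini-Hochberg column; raw p-values stay primary.

Delta sign convention: by default deltas are *derived minus ancestral*
(`to_minus_from`); `--convention from_minus_to` flips every sign.  The
two-tailed p-value is identical either way.

## Python API

```python
from dirsel import (
    builtin_library, diff_aligned, run_panel, whole, matrix_report,
)

lib = builtin_library()                      # 25 scales
rl = diff_aligned(seq_a, seq_b)              # replacements + filter counts
part, pooled = whole(rl)
results = run_panel(pooled, lib)             # one t-test per scale
print(matrix_report({part.name: results}, lib, "grid"))
```

`dirsel.simulation` provides the bundled Pan/Homo SAGE1 worked example
(`sage1_fixture()`, 15 replacements) plus seeded null and biased replacement
generators used for calibration.

## Data provenance

Built-in scale values are sourced from the AAindex database; each scale's
`source` field records the entry accession (e.g. hydropathy `h` =
KYTJ820101, Kyte-Doolittle).  Four scales with no matching AAindex entry
(helical contact area, buriedness, compressibility, rms fluctuational
displacement) use closest-concept entries explicitly marked `(proxy)` in
their source field.
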