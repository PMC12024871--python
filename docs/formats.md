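# File formats

All files are UTF-8, tab-separated unless noted, with `#` comment lines
skipped on read.

## PPI edge list (input to `build --ppi`)

At least three columns: `id_a  id_b  confidence` with confidence in [0, 1].
Column positions are configurable in the library (`read_ppi_edges`); no
identifier mapping is performed.

## Cross-layer edge list (input to `build --cross`)

`protein_id  partner_id  partner_layer  source` with
`partner_layer ∈ {lipid, metabolite}` and `source ∈ {enzymatic, gwas}`.
An optional header row with exactly these names is tolerated.  Partners are
expected to carry the `SLM:` (lipid) or `Pubchem:` (metabolite) prefix; a
missing prefix is a warning, not an error.

## Network pair (`<prefix>.nodes.tsv`, `<prefix>.edges.tsv`)

Both files start with the version stamp line `# omicsmap-network v1`
followed by a header row.

* `nodes.tsv`: `id  layer`
* `edges.tsv`: `a  b  kinds  confidence` — endpoints in sorted order,
  `kinds` a comma-joined provenance list (`ppi` or subset of
  `enzymatic,gwas`), confidence empty for cross-layer edges.

Rows are sorted and floats use shortest round-trip formatting, so rewriting
an unmodified network is byte-identical.  A stamp mismatch on read is a hard
error.

## Ground truth (`<prefix>.truth.tsv`, written by `simulate`)

`id  t  r  theta` — birth index (−1 for attached lipids/metabolites whose
row carries the anchor position), final-snapshot radius, angle.

## Coordinate table (`embed --out`, input to `cluster`/`rank`/`plot`)

`id  layer  r  theta` with r ≥ 0 and θ canonicalized into [0, 2π) on read
(adjusted rows are counted in the log).  A missing `layer` column is
inferred from the id prefix, so externally produced tables with only
`id r theta` load as well.

## Cluster table (`cluster --out`)

`cluster  theta_start  theta_end  id` — one row per member; labels are
1..k ordered by sector start angle; the arc [theta_start, theta_end) may
wrap through 2π.

## Annotation (input to `enrich`)

Either a two-column TSV `term  id` (one pair per row) or a GMT file
(`term  description  id1  id2 ...`, selected by the `.gmt` extension).

## Enrichment table (`enrich --out`)

`term  term_size  overlap  p_value  p_adjusted  significant`.

## Ranked associations (`rank --out-prefix`, one CSV per non-input layer)

Comma-separated: `rank,id,score,evidence,distance_sum` where `evidence` is
`source:distance` pairs joined by `;` with 6-decimal distances in ascending
order, and `distance_sum` keeps full precision.

## Tissue expression (input to `rank --expression`)

`protein_id  tissue  ntpm`; proteins pass the filter when ntpm ≥ cutoff
(default 10, inclusive) in at least one selected tissue.

## User subset (input to `rank --input`)

Newline-separated molecule identifiers of a single omics layer (UniProt
accessions, `SLM:` lipid ids, or `Pubchem:` CIDs).
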