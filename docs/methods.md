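# Methods

## Coordinate system and data model

All positions are 1-based residue numbers; intervals are inclusive on both
ends.  The canonical frame is the fast skeletal 2× heavy chain (MYH1), whose
motor region spans positions 1–813 here (through the end of the lever-arm
interval).  A consolidated variant record holds one rs cluster: gene,
isoform, native residue, one or two alternative substituted residues, one or
more alternative isoform-frame positions, per-subpopulation genotype
observations, and a disease flag.  Multi-allele clusters count as one
position throughout, and disease flags are curated data keyed by rs id —
the parser never infers disease status from content.

Three position notations occur in curated catalogs: exact (`D108E`),
upstream-bound (`P(<82)L` — the substitution lies somewhere before position
82, with no homology anchor), and ambiguous range (`Y(389-390)H`).  The two
inexact notations are parsed faithfully and classed *unmappable*: no exact
reference position is ever fabricated for them.

## Ingest

The raw dialect is a six-column flat table (cluster id, gene, function
class, base change, amino-acid change, peptide position), tab- or
whitespace-delimited, with `X -->Y` change fields.  Continuation rows carry
a blank cluster id; verbatim duplicate rows are deduplicated silently (the
dialect demonstrably repeats them); malformed rows go to an error report
with line numbers rather than being dropped; rows with an unrecognized
function class are kept but flagged.  Consolidation groups rows by rs id,
collapsing alternative alleles into the substituted-residue set and
alternative splice-frame positions (e.g. the smooth-muscle loop-1 insert
shifting every downstream position by 7) into the position set.
Consolidation is idempotent, and the output record count always equals the
number of distinct rs ids passing the function-class filter.

## Reference mapping

Cross-isoform coordinate mapping uses global (end-to-end) pairwise alignment
with affine gap penalties — three-state Gotoh dynamic programming with
BLOSUM62, gap open −11 for the first gap residue and −1 per extension
(the standard protein-BLAST costs), end gaps penalized.  Ties in the DP are
broken in a fixed order (diagonal, then gap-in-reference, then
gap-in-isoform), so maps are deterministic byte for byte.  The row
recurrences are vectorized; the within-row gap state is computed by a
cumulative-max transform, giving O(nm) time with O(n·m) memory for the
traceback matrices (~2 MB at motor-domain lengths).

A variant's isoform position translates through the alignment map only if
(i) the position is aligned (not in a gap), and (ii) the local identity over
a 21-residue window of alignment columns centred on it is at least 50 %.
Otherwise the variant is unmappable.  The window and floor are single config
values; the defaults are deliberately permissive — at the >85 % identities
typical of myosin isoform pairs the gate only trips in genuinely
non-homologous stretches.  When a record carries alternative numbering
frames, the frame whose isoform residue matches the record's native residue
is used.  Whole-map identity below 50 % additionally flags the map
low-homology.

In fixture mode (catalog only, no sequences) the printed reference-frame
position is accepted directly, with the printed "reference residue if
different" column populating the differs flag.  Sequence mode and fixture
mode agree wherever both are available, which the synthetic-data tests
verify on planted families.

## Domain model

The model is an editable JSON data file.  Core-functional intervals:
β-strands β1 116–127, β4 170–180, β6 248–257, β7 265–271, β5 458–468,
β3 671–678; SH3 30–80; Switch 2 helix 469–509; SH2/SH1 hinge 688–715
(28 residues); converter 716–772; lever-arm 773–813; C-loop 363–377;
Myopathy loop 404–417; Loop 2 626–651; Loop 3 568–580; hydrophobic actin
contacts 529–560 and 652–661.  Curated vicinity residues encode the "near"
assignments made by structural inspection, which no interval rule
reproduces: 88/89/98/108 near β1, 445/447 near β7, 681 near β3, 258 between
β6/β7, Switch 1 at 240/246, Switch 2 at 469, 378 near the C-loop, 621 near
Loop 2, and 534/655 inside the hydrophobic contacts (kept for grouping).
Switch 1 and Switch 2 have no printed intervals of their own and exist only
as curated residues.  Coarse regions N-term 1–219, U50 220–468, L50 469–620
plus a residual C-terminal segment 621–813 tile the frame so that every
position receives exactly one label.  Loop 1 (200–220) and the U50a/U50b
sub-intervals (145–361, 362–462) are carried as annotations that never
affect assignment.

Precedence at a position: curated vicinity residue, then core-functional
interval, then coarse region.  Curated entries outrank intervals because the
per-residue assignments are the more specific statement — residue 469 is
Switch 2 (β-sheet group) even though it also begins the Switch 2 helix
interval, and counting it in the helix would misstate both groups' burdens.
Position 701 carries an additional "swivel" tag.

Groups for burden counting follow the catalog's section structure: the six
strands plus Switch 1/2 and all β-sheet vicinity residues form
`beta_sheet_region`; the five actin-binding elements plus near-Loop-2 form
`actin_binding`; the Switch 2 helix, hinge, converter, lever-arm and SH3 are
their own groups.  Note the six printed strand intervals sum to 59 residues;
the package reports interval sums and does not attempt to reconcile them
with any other figure.

`spatial_vicinity` checks a vicinity call on user-supplied coordinates
(PDB via gemmi): *near* iff the minimum heavy-atom distance between the
residue and any domain residue is ≤ 8.0 Å.  The default cutoff brackets the
most distant curated vicinity residue (~7.5 Å).  Hydrogens are ignored;
the verdict is monotone in the cutoff.  No homology modeling is performed;
a structure, when used, is supplied by the user.

## Population summaries

AHP is the arithmetic mean of the non-missing per-subpopulation
heterozygous percentages (computed with `math.fsum`, so it is exactly
order-invariant); it is missing when no subpopulation contributes a usable
value, and subpopulations without data never drag the average toward zero.
Missing is distinct from zero end to end, with one exception: the plotted
position track renders missing AHP as 0 while the underlying data value
stays missing.  Observations marked discordant are excluded from both the
AHP and the homozygote flag (Y if any substituted homozygote was reported,
N if data exist and none were, unknown otherwise — note AHP 0 and flag Y
can coexist).  No allele-frequency estimation or Hardy–Weinberg inference
is attempted; the module only summarizes reported percentages.

## Categorization and tolerance classification

Category precedence is total and deterministic:
`disease_implicated` > `unmappable` > `in_domain` (interval or curated
vicinity) > `outside` (coarse region only).  Conservation holds by
construction: total = disease + unmappable + in_domain + outside, and
in_domain equals the sum of per-group benign burdens.

Domain classification defaults: `too_sensitive` if a group has at most 1
benign SNP and at least 1 disease mutation; `too_robust` if it has at least
2 benign SNPs; otherwise unclassified.  Coarse regions are never classified.
The thresholds are config values; raising the AHP threshold never adds probe
candidates and loosening the robust threshold never removes a robust label.
Function-neutrality is reported per variant, not per domain: the candidate
list holds variants with AHP ≥ 0.5 % (the plotted-bar floor), and records
whose substituted allele is homozygous in all tested subpopulations are
reported separately as reference anomalies rather than as candidates.

Substitution chemistry comes from packaged per-residue tables: charge at
pH 7 (His treated as neutral), a three-class polarity scale
(nonpolar/polar/charged), theoretical maximum accessible surface areas
(Tien et al. 2013) for the size change, and the Pace & Scholtz (1998) helix
propensity scale, with ≥0.05 kcal/mol penalty change calling a substitution
helix-stabilizing or -destabilizing.  The packaged scales reproduce the
expected calls for all eight Switch-2-helix substitutions in the catalog.
Size changes are meaningful in sign and class; absolute Å² values are
scale-dependent and tests treat them as such.  Special flags cover proline
introduction, glycine loss (the G701 swivel case), cysteine introduction,
and aromatic introduction.

## Synthetic data

The generator emulates the structure of the real inputs, not their biology:
a random reference sequence (uniform over the 20 residues), isoforms derived
by per-site substitution at rate 1 − target identity (uniform exchange
excluding the native residue — the simplest model adequate for
coordinate-mapping tests) and by planted insertions/deletions with exact
truth maps; variants planted per domain as a Poisson process with a stated
per-residue rate; AHP drawn from a mixture of point masses at missing
(0.35) and zero (0.25) with an Exponential(mean 5 %) positive component
capped at 50 % — matching the catalog column's qualitative shape (many
missing/zero values, positive tail to 50 %); disease and homozygote flags
Bernoulli.  The dbSNP validation process is not modeled; the AHP mixture is
a testing convenience, not a claim about the database.  Base changes in the
emitted cluster tables are consistent annotations only — no codon structure
is simulated.

What passing tests show: the pipeline recovers planted reference positions,
domain labels, categories, and per-domain counts exactly for all variants
outside indel-disturbed windows (a ±10-residue halo around each indel edge,
where alignment columns are legitimately ambiguous), and the dialect
round-trips losslessly.  What they do not show: robustness to real
low-complexity sequence, to isoform pairs below ~85 % identity, or to
database curation artifacts beyond those the dialect itself exhibits.

Default study-scale conditions used by the tests and examples: reference
length 813 (the motor-domain frame), 2–3 isoforms at 92 % target identity
with a 7-residue insert (the loop-1 analogue), per-domain rates of
0.05–0.2 variants per residue.  Identical seeds give byte-identical outputs
(`numpy.random.default_rng` throughout).

## Pipeline and reproducibility

A run is a single serializable config (paths, thresholds, seed, output
directory); its SHA-256 hash is echoed into every artifact (`summary.json`,
`burdens.tsv`, `track.tsv`, `domain_track.json`, `annotated.tsv`), and the
log records per-stage record counts satisfying the conservation invariant.
Re-running an identical config reproduces identical bytes.  Fixture mode is
the desk-scale reproduction of the published analysis; sequence mode is the
alignment-exercising path used by the synthetic recovery tests.  Any stage
error aborts with the stage name and offending record.  Rendered figures
are deliberately out of scope: plot data are emitted as text tracks, and no
networked retrieval exists in the tested path.

## Known limitations

* The reference frame is defined by the packaged domain model (and, in
  sequence mode, by whatever FASTA the user designates as the reference);
  no external accession is resolved.
* The homology gate's 50 %/21-residue defaults are calibrated to the
  curated catalog's mapping outcomes, not derived from first principles.
* Curated vicinity residues are data, not a rule; applying the model to a
  non-myosin family requires editing the JSON.
* The tolerance classification is a threshold rule on raw counts; no
  enrichment test against a null SNP distribution is performed.
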