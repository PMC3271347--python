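# Methods

This note documents the models, conventions and numerical choices behind
`pathconsensus`, in the spirit of a methods appendix: what the pipeline
assumes, which knobs matter, what the synthetic benchmark does and does not
emulate, and where the design was genuinely open.

## Entity resolution

### Metabolite identity cascade

Two metabolite records are held to denote the same compound by the first
applicable rule:

1. **Override pairs.** Hand-curated descriptor pairs
   (`namespace:accession` or `snapshot:local_id`) force a match regardless of
   everything below, including the generic/specific guard. Overrides exist for
   cases automated matching cannot decide — the canonical example being
   enzyme-bound versus unbound forms of the same cofactor (lipoamide-E vs
   lipoamide), which carry different primary accessions on purpose. Because
   overrides are curator assertions of identity, they are allowed to beat the
   guard; the order of override vs guard is a design choice documented here.
2. **Generic/specific guard.** A class placeholder ("an alcohol") never
   matches a specific compound ("ethanol"), even when a database has linked
   the class accession to both. Class *instances* are ordinary records and
   match normally.
3. **Primary accession (KEGG-Compound-style), stop rule.** When *both*
   records carry one, the comparison is final either way: equal accessions
   match; different accessions block the pair even if secondary identifiers or
   names agree. Rationale: the primary namespace is the curated, most
   trustworthy cross-reference, and it deliberately lumps protonation states —
   softening the stop rule would let noisy secondary cross-references overrule
   it. The override mechanism exists precisely for the rare exceptions.
4. **Secondary identifiers.** Any agreeing namespace among KEGG Glycan,
   ChEBI, PubChem Compound, CAS matches. A *disagreeing* secondary namespace
   does not block the pair (only the primary comparison is a stop rule);
   conflicts simply fail to support a match and the cascade falls through to
   names. KEGG Glycan is treated as an ordinary secondary namespace.
5. **Name + formula.** A shared normalized name matches only when both
   records also carry chemical formulas and those are equal; a missing formula
   cannot satisfy the requirement (`name_requires_formula`, default on).
   Names are multi-valued; any shared synonym counts. Within one snapshot, a
   normalized name attached to more than one distinct formula is quarantined
   from matching entirely (ambiguous synonym).

Name normalization: Unicode NFKC, casefold, all whitespace and punctuation
removed. No transliteration — a Greek α and the word "alpha" stay distinct,
because silently equating them would manufacture matches the databases never
asserted. Formulas are parsed as Hill-style element counts; under
`h_tolerant_formula` the H count is excluded from the equality, absorbing
protonation-state conventions (databases that store the pH 7.2/7.3 charged
form versus the neutral form). Unparseable formulas fall back to exact string
comparison.

Matches are closed transitively (union–find): if A~B on CAS and B~C on ChEBI,
then A~C. The implementation prunes candidate pairs by blocking on shared
identifier values and normalized names — sound because every cascade route
requires a shared value — and the test suite checks the resulting partition
equals connected components of the brute-force all-pairs match graph.
Within-snapshot matching is performed (needed for duplicate collapse and
closure) but a snapshot contributes at most once per class to any count.

### Reactions

A reaction's identity is the unordered pair of its sides, each side the *set*
of metabolite-class representatives. Three things are deliberately ignored:

- **Direction** — databases disagree on writing conventions and
  reversibility; the same reaction written in both directions in one database
  counts once.
- **Compartments** — compartment annotation density varies too much across
  sources to participate in identity.
- **Stoichiometric coefficients** — stored but not compared; balancing
  disagreements (which are common) must not block matches. This was a
  genuinely open choice; identity on participant sets was adopted and
  coefficients are retained in the data model should a stricter mode ever be
  wanted.

Before comparison, members of the configured **ignore set** are removed from
both sides. The default ignore set is {e⁻, H⁺, H₂O} ("relaxed" matching) —
the three species whose bookkeeping differs most across databases; an empty
ignore set gives strict matching; single-pathway case studies conventionally
ignore H⁺ only. Ignore labels resolve to concrete metabolites via their
primary accession (C05359 / C00080 / C00001) or normalized name, then to whole
equivalence classes. A reaction whose sides coincide or become empty after
removal (e.g. pure water transport under relaxed matching) has a degenerate
signature: it is excluded from statistics and listed with a reason code.

Lumped multi-step conversions are *not* automatically aligned with their
net reaction — there is no reliable automated criterion for deciding whether
a one-step and a three-step description mean the same conversion, so such
pairs count as disagreement (the synthetic benchmark plants them to measure
exactly this degradation).

### Genes and EC numbers

Genes compare on a single shared identifier namespace; protein-complex
structure is deliberately flattened (no distinction between a gene encoding a
whole catalyst and one encoding a subunit), since only some databases model
complexes syntactically. EC numbers compare complete (all four parts) or at
the three-part class level; partials are excluded at both levels.

## Statistics

`consensus = |∩ C_i| / |∪ C_i| × 100`; `majority(k)` is the fraction of the
union in ≥ k databases; both derive from the occurrence histogram, which is
reported in full. All printed percentages use **round-half-up to whole
percent** — the convention was adopted because it reproduces every percentage
of the reference comparison tables from their printed counts; the original
convention is not stated anywhere, so this is an inference, verified in tests,
not a known fact.

Pairwise tables are computed from partitions **rebuilt per pair**: with all N
databases in one partition, transitive closure through a third database could
merge entities of a pair that share no direct match route, inflating pairwise
overlap. Combination analyses attach to each consensus reaction class a
per-database gene set and EC set (the union over that database's member
reactions of the class) and bucket classes by full/partial/no agreement, with
an `additional_genes` tag when a common core exists but some database links
extra genes.

Restricted comparisons rerun the entire pipeline on a sub-snapshot: a pathway
scope selects reactions of one named pathway per database (with an alias table
when databases name it differently), a category scope selects reactions
carrying at least one of a set of category labels. For pathway scopes the
per-reaction-class gene/EC agreement breakdown is reported next to the
across-subset comparison (genes matched within matching reactions first,
across the subset second).

## Categorization and the core subset

Pathways are assigned to a closed vocabulary of eleven labels: nine
metabolism categories patterned on the KEGG hierarchy, `miscellaneous`, and
`transport`. Entities inherit the categories of all their pathways. A
reaction is *transport* iff its participants span more than one compartment;
absent compartments collapse into one shared pseudo-compartment so sparsely
annotated databases are not spuriously full of transport reactions. A
reaction is *macromolecular* iff any participant is flagged as a protein.

The core subset keeps reactions carrying at least one of six categories
(amino acid, carbohydrate, energy, lipid, cofactors-and-vitamins, nucleotide
metabolism), drops pathway-less reactions (they cannot be categorized),
transport reactions, and — only for databases configured for it, since only
some annotate protein participants — macromolecular reactions. Reactions
whose pathways map only to `miscellaneous` are excluded from the core by
construction. The filter is idempotent and its output is a valid snapshot.

## Interchange format

Snapshots are single JSON documents (`schema_version 1.0`; top-level arrays
`genes` / `metabolites` / `reactions` / `pathways`; reaction sides as
`[metabolite_id, coefficient]` pairs), with a TSV-bundle directory dialect for
hand-authored fixtures (one file per array; pipe-delimited list cells). Writes
are canonical (records sorted by local id, keys sorted), so
write→load→write round-trips byte-identically. Identifier syntax per
namespace is checked against configurable patterns. SBML/BioPAX input is
refused with a pointer to the interchange format — source-specific ETL is out
of scope by design.

Identifier update tables (per-namespace `old → new`, empty target = obsolete)
are applied before comparison: transferred identifiers are replaced, obsolete
identifiers are removed *from the record*, never the record itself — the
entity can still match via other routes. Transfer maps must be pre-flattened
(no chains), which makes the update idempotent.

Set/class-valued reactions are instantiated positionally: the first member of
each set on the left pairs with the first member of each set on the right
("first member … and so on"). `first_member` takes index 0; `all_members`
emits one instantiated reaction per index, bounded by the shortest set — the
natural generalization of the positional rule, adopted here as a package
choice since only the first-member behaviour is externally specified. When
both sides carry sets in unequal numbers the pairing is ill-defined; such
reactions are left unexpanded and flagged, never guessed.

## Synthetic benchmark

`generate_ground_truth(n_reactions, n_pathways, seed)` builds a random
bipartite metabolite–reaction network: ~1.6 core metabolites per reaction,
each with a full identifier bundle (synthetic accessions in a reserved
`C7xxxx/C8xxxx/C9xxxx` block), a unique base name plus synonym, and a random
formula; shared currency metabolites (ATP/ADP, NAD⁺/NADH, GTP/GDP, phosphate,
H⁺, H₂O) reuse their real primary accessions so default ignore-set resolution
works unchanged, and are attached to ~65% of reactions — which also makes
their degree distribution dominate the median metabolite degree, as in real
networks. One three-step linear chain per 20 reactions (with dedicated
intermediates) is annotated as lumpable, with its net reaction precomputed.
Relaxed reaction signatures are unique by construction, so the perturbations,
not generator collisions, are the only source of matching ambiguity.
Optional fractions of cross-compartment transport reactions and
protein-participant reactions exist for the categorization filters and are
off by default, keeping the truth oracle exact for recovery tests.

`derive_snapshot` applies, independently per eligible entity: reaction
inclusion (`p_cov`); per-namespace identifier dropout; name variants (40%
case/punctuation edits and 30% synonym swaps, both recoverable by
normalization, 30% drawn from a deliberately unrecoverable "hard" pool to
exercise missing-match paths); protonation shifts (±1 H in the formula plus a
charge-suffixed *additional* name — the base name stays in the multi-valued
list so the H-tolerant flag has an observable effect, while the formula
difference blocks strict name+formula matching); chain lumping (`p_lump`
replaces a whole route by its net reaction); alternative cosubstrates (a
duplicate reaction with ATP/ADP swapped to GTP/GDP — the pair is fixed, not
sampled, so the alternative has one identity across snapshots);
generic-metabolite substitution; obsolete-identifier injection (the snapshot
gets an outdated accession, and the matching transfer/obsolete table rides on
the truth ledger so update application reverses it); direction flips;
proton/water imbalance; and pathway-assignment dropout. H₂O and H⁺ themselves
are exempt from metabolite-level perturbation — a database that cannot
recognize water is not worth emulating, and perturbing them would conflate
ignore-set resolution failure with the disagreement being modelled.

The truth ledger maps every emitted entity to its ground-truth id (route id
for lumped reactions) with its perturbation tags, so expected overlap
statistics are computable without the matcher. Closed form used in tests: two
snapshots at coverage `p` have expected pairwise reaction consensus
`≈ 100·p/(2−p)` (at p = 0.5: 33.3%).

What the generator does **not** emulate: mass/charge balance, thermodynamics,
biochemical realism of the network topology beyond currency-metabolite
structure, cross-database correlated curation (real databases copy from each
other), and real accession registries. Passing recovery tests therefore show
the *matcher* is sound under the cataloged perturbation types, not that real
databases would yield any particular consensus value.

## Determinism and problem sizes

All randomness flows through seeded generators (per-snapshot streams derived
from the profile seed and a CRC of the snapshot name); matching and reporting
are deterministic by sorted canonical serialization everywhere, and identical
configs produce byte-identical artifact directories (verified byte-for-byte in
tests, excluding the run log, which echoes the differing output paths). Test
and acceptance problem sizes — 40–100-reaction truths, 2–3 snapshots, 20–50
seeds, fuzzed fixtures up to 300 metabolites — were chosen as the smallest
scales at which every perturbation type occurs multiple times per run; the
suite completes in well under a minute.

## Known limitations

- Lumped-versus-net reaction correspondence is detected only via the
  synthetic ledger, never inferred from data (by design).
- The name route depends on formula annotation; databases without formulas
  fall back to identifiers only, and `name_requires_formula=False` trades
  false negatives for false positives globally rather than per record.
- The secondary-identifier step accepts any one agreeing namespace; records
  with several conflicting namespaces are matched on the agreeing one and the
  conflict is not currently surfaced in reports.
- Pairwise mode rebuilds partitions per pair, so large N makes the pairwise
  table quadratic in matching cost.
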