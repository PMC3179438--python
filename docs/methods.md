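# Methods

`deidkit` de-identifies categorical, discharge-abstract-style microdata for
public release. This note documents the model, the algorithmic choices, the
synthetic-data conditions the tests run under, and the limits of what those
tests show.

## Threat model and risk criterion

A released file is a random sample (sampling fraction α) from a population
database. An adversary knows some quasi-identifiers about people in the
population — demographics (province, age group, gender) plus, at an assumed
level of detail, clinical attributes such as the responsible diagnosis or
principal intervention. Three attacks are modelled:

1. **Single match against a registry.** The adversary holds an identified
   population registry covering demographics only, and matches one randomly
   chosen record. For a demographic equivalence class *j* with provincial
   population count *C_j*, the probability of a correct match is 1/*C_j*.
   The headline measure per province is the population share in classes
   exceeding the tolerance τ:  (1/N_p) Σ_j C_j · I(1/C_j > τ).
2. **Match everyone against a registry.** The expected number of correct
   matches is bounded by Σ_j f_j/C_j, where f_j is the class size in the
   released file. Under proportional sampling f_j = αC_j this collapses to
   Q·α for Q classes — a closed form needing only the class count and the
   sampling fraction.
3. **Target a specific person.** An acquaintance-adversary who knows a
   target's quasi-identifiers and finds a matching class picks one of its
   records; the probability of being right is 1/F_j, with F_j the class
   size in the *population* on the full released quasi-identifiers. The
   release criterion is therefore F_j ≥ k = ⌈1/τ⌉ for every class — the
   k-anonymity condition, with τ ∈ {0.04, 0.05} the conventional public-release
   tolerances (k = 25 and 20) and τ = 0.2 (k = 5) the trusted-recipient
   baseline. ⌈1/τ⌉ is evaluated in exact rational arithmetic on the decimal
   literal, so 0.04 gives 25 rather than a float-round-off 26.

Only *correct* re-identification is scored. Attack 3 is the binding attack;
attacks 1 and 2 are assessed with the closed forms and validated by the
Monte Carlo simulator (below).

## Generalization hierarchies and attackable combinations

Each hierarchical quasi-identifier carries a DAG of named levels, rank 1 the
most detailed, with many-to-one value maps on the edges. The diagnosis
hierarchy is the instructive case: the code (MRDx analogue) generalizes along
a totally-ordered chain to its block and chapter, and along a separate
*branch* to a case-mix group, which is not order-comparable with the block.
All recoding is table-driven (interval codings like 5-year age bins or
length-of-stay weeks are precomputed value maps), so every transformation is
auditable and composition/idempotence are structural facts.

The released file carries **one column per released level**, letting each
analyst pick their own precision. Consequently every level the adversary
could know must be protected separately: for knowledge level Q, the
*evaluated levels* are all levels with rank ≥ rank(Q). Rank, not
reachability, defines the set — a branch terminal like the case-mix group
has no coarser image, yet the coarser block is still independently knowable.
With chain-skipping enabled (the default), a level reachable from another
evaluated level through totally-ordered edges is dropped from evaluation and
handled by propagation instead. The attackable combination set is the cross
product of evaluated levels across hierarchical quasi-identifiers, each
crossed with the full demographic set; emission order is lexicographic in
(QI declaration order, level rank) for reproducible audits.

Release planning follows the familiar two-case rule: if the analysts accept
a level M no finer than the adversary's Q, suppress and release at M; if
they need M finer than Q, suppress at Q and release at M with downward
propagation. Propagation is per-record: a record whose cell at the
suppression level is blanked has its finer-level cells blanked (the
suppressed value must not be re-derivable) and, along totally-ordered edges
only, its coarser chain cells blanked (the skipped evaluations). Branch
levels never propagate to each other.

## The two-phase suppression algorithm

Given k, a *mole* is an equivalence class of size < k on some evaluated
combination. The algorithm blanks individual cells (local cell suppression)
rather than records or columns:

* **Phase 1** blanks every category with support < k wherever it occurs.
  Such values cannot sit in a large-enough class, so removing them
  value-wise is always necessary. Supports count non-sentinel cells, and
  blanking one value never changes another's support, so one sweep per
  column reaches the fixed point. Weights are *not* applied in phase 1.
* **Phase 2** orders combinations by descending mole count (ties by
  declaration order). Within a combination it repeatedly selects the value
  with the smallest weighted support wsup = sup·w (ties: column position in
  the combination, then category label) and blanks it inside every class of
  size < k that contains it; supports and the class index are recomputed
  after every visit. A higher weight therefore shields a column.

The suppression sentinel is a **distinct grouping value**: records blanked
on a column form their own classes. This matters twice. First, it matches
the worked example, where records whose birth decade was suppressed earlier
sit in singleton classes at the diagnosis step. Second, it forces the
honest fixed point: "no moles at all" is unachievable (an all-sentinel
class may stay small forever), so strict mode stops when *no mole contains
a non-sentinel cell*. At that point every surviving value also has support
≥ k, because a class containing a value can never be larger than that
value's support.

Two stopping rules are exposed. `strict` (default) additionally sweeps the
whole combination list until a full sweep changes nothing — suppressing
cells for one combination can open new moles on an earlier one through
their shared columns, and a single pass provably leaves residuals on
skewed data. `walkthrough` performs exactly one ascending pass per
combination; it exists to replay the published worked example exactly and
is what the fixture tests use.

The `complete` baseline is the identical machinery with one combination
holding every quasi-identifier column. On overlapping hierarchy levels it
is forced to destroy an entire column (both levels in one class key means
every class is unique), which is precisely the pathology the combinations
formulation avoids — the four-record worked example reproduces this
contrast exactly (0 vs 4 cells).

Every blanked cell is logged as an audit entry (record, column, value,
phase, combination, class size, pass); replaying the audit on the input
reproduces the output bit-for-bit, which is tested.

### The walkthrough fixture

The 27-record example's diagnosis column is not published cell-by-cell; the
fixture constructs an assignment satisfying every documented constraint
(four singleton diagnoses; three support-3 diagnoses each a single class of
three; the acute-respiratory split {8} vs {16,19,24}; external injury of
support 4 with {10,14} a size-2 class; metabolic disorder of support 6 with
ids 23 and 25 in singleton classes), re-verified on every construction. The
documented constraints are mutually over-determined at one point: no
assignment over these sex/decade columns can confine the metabolic pass to
ids 23 and 25 alone while also leaving {10,14} as the only small class at
the 1960s pass — the four non-singleton metabolic records would need a
same-sex-same-decade cell of four, and the only such cell is needed intact
for the 1960s pass. The fixture resolves this minimally: the metabolic pass
suppresses one additional singleton (id 9) alongside 23 and 25, and every
other pass, including phase 1 and the two no-op passes, replays
cell-for-cell. Tests assert that exact feasible replay.

## Information loss

Two metrics are reported. **Suppression extent**: per-column % of cells
blanked, % of records with ≥ 1 blanked quasi-identifier cell, and total %
of quasi-identifier cells blanked (the exact mean of the per-column
percentages — reconciled in the report). **Non-uniform entropy**: each
cell contributes the conditional surprisal of its original value given its
released value, with the conditional estimated from the *original* empirical
distribution — a cell generalized to g contributes −log₂(n(v)/n(preimage of
g)), a suppressed cell −log₂(n(v)/n), an unchanged cell 0. Estimating the
preimage from the recoding map rather than from the surviving released
cells is what makes the metric monotone under additional suppression; it is
also non-decreasing under any generalization, with equality exactly for
bijective relabelings, and additive over records and columns. All three
properties are unit-tested, by brute force on small random tables where
appropriate. Because bits lack an interpretable unit, reports are expressed
relative to a designated baseline run (baseline = 100%); display values are
rounded to one decimal with raw values retained.

## Synthetic data: what it emulates and what it does not

The generator produces structurally DAD-like categorical microdata: 10
provinces (territories grouped), 20 five-year age groups top-coded at 90+,
5 gender codes of which two carry ~98% of the mass, optionally 25
length-of-stay weeks, a four-level diagnosis hierarchy and a two-level
intervention hierarchy with ~46% of records carrying no intervention. Value
frequencies are Zipf-like (exponent 1.0 by default), producing the
small-class tail the algorithm exists to repair. Code inventories default
to a ~1/18 scale of the national ones (500 diagnosis codes → 30 case-mix
groups / 29 blocks / 19 chapters; 480 intervention codes → 31 short codes)
so that class-size structure, not raw volume, is preserved at test sizes.

Not emulated: clinical correlation between demographics, diagnosis and
intervention; seasonal/temporal structure; realistic marginals. Passing
tests therefore demonstrate algorithmic correctness (fixed points, audit
integrity, closed-form agreement), not that suppression percentages on
real national data would match the synthetic ones — at a few thousand
records over these category counts the suppression fraction is necessarily
far higher than on a multi-million-record population file.

The identified population generator (default 10,000 individuals across a
full crossing of 4 provinces × 10 age groups × 2 registry sexes, Zipf
weights, every stratum non-empty) backs the matching simulator. The
simulator draws the released file and registry as independent simple random
samples per replicate, matches within strata, and scores correctness by
true identity. Attack-1 agreement is assessed with a pooled z-statistic
(per-stratum null-binomial SEs pooled over strata) rather than dozens of
simultaneous per-stratum 3-SE tests, which would fail by chance alone;
attack-2 agreement compares the replicate mean to the realized Σ f_j/C_j
within 3 standard errors at 1,000 replicates.

## Numerical and procedural choices

* Record ids: taken from an id column when present, else sequential 1-based;
  categories are case-sensitive exact strings, trimmed of surrounding
  whitespace only.
* The sentinel is a reserved token rejected in fresh input, so it cannot
  collide with data; on CSV output it is rendered as a configurable text
  (empty field by default).
* Tie-breaks everywhere are deterministic (declaration order, then label;
  suppression order within a class by record id), so identical inputs give
  identical audits.
* Degenerate inputs: empty tables flow through every stage vacuously; k = 1
  suppresses nothing; a table already k-anonymous yields an empty audit.
* Problem sizes in the test and acceptance runs (tables of up to 5,000
  records, 50-table property battery, 1,000 simulator replicates) were
  chosen to exercise the asymptotics the implementation claims — runtime is
  measured across sampling fractions 0.1–0.9 and reported, not asserted.

## Known limitations

* Identity disclosure only: no l-diversity-style protection against
  attribute disclosure.
* The heuristic carries no approximation guarantee on suppression counts;
  it is designed for linear-time behaviour on large files, trading
  optimality for scalability.
* Census counts are taken as pre-weighted; survey weighting happens
  upstream of the toolkit.
* Continuous variables must be discretized (as interval value maps) before
  use; files are processed in memory.
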