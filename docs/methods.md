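# Methods

This note documents the models, conventions, and numerical choices behind
`ohcnet`, and what its synthetic benchmark does and does not establish about
real online-health-community (OHC) data.

## Tie rule and network construction

A directed tie A→B encodes information flow: B accessed content contributed
by A. Concretely, for the public channels (BL, MB, GD) every access event on
a piece of content creates a tie from the content's author to the reader;
for private messages a tie requires a *read* event — a delivered but unread
message moves no information and creates no edge. Replies are ordinary
content with their own access events, so a reply thread naturally produces
reciprocated ties. Threaded structures (group discussions, blog comment
threads) are represented at the event level: reading a thread is logged as
one access event per post read, so a reader acquires incoming ties from all
authors whose posts they actually accessed. Self-accesses are discarded.

Edges carry `first_ts`, the minimum timestamp over all qualifying events for
that ordered pair; because it is a minimum, construction is invariant to the
ordering of input rows. A user belongs to a layer's node set iff they have at
least one incident tie there, and the aggregated network is the exact union
of layer nodes and edges with the minimum first-contact time per edge.

## Topology conventions

* **Density** uses N = nodes with degree > 0 (not the registered-user
  count): E / N(N−1), directed, no self-loops.
* **Reciprocity** is dyad-based: the fraction of connected dyads (unordered
  pairs with ≥ 1 tie) that are mutual (ties both ways). Under this
  convention mutual = E − connected dyads, an identity the test suite checks
  on every generated network. The edge-based alternative 2·mutual/E is *not*
  what this package reports.
* **LSCC** size ties (possible only in tiny graphs) break toward the
  component containing the lexicographically smallest member — a degenerate
  but deterministic rule.
* **Mean shortest path** within the LSCC is exact by default (BFS from every
  member, averaged over ordered pairs). For LSCCs above 20,000 nodes the
  report falls back to uniform source sampling (1,000 sources) and flags the
  estimate as approximate; `exact_paths=True` forces the exact computation.

## Cross-layer similarity

Multiplexity counts unordered pairs connected (either direction) in exactly
k layers. Degree-rank correlations use Spearman ρ with average ranks on
ties and the t-distribution p-value approximation; the default node scope is
the union of the two layers' active nodes with zero filled in for the layer a
node is absent from. This is the only scope defined for every pair of
layers; the stricter intersection-of-active-nodes scope is available via
`scope="intersection"`. Jaccard overlap is computed on directed ordered-pair
edge sets, since ties are directed objects.

## Tie coevolution

Each connected pair is reduced to per-layer first-tie times (minimum over
both directions), and the sequence of distinct layers sorted by that time.
Analysis is pair-level and direction-agnostic so that the first-tie
denominators equal the multiplexity pair total exactly — a conservation
identity asserted in the tests. Equal first-tie times across layers break by
the fixed order BL < MB < GD < PM (configurable); with the generator's
globally unique integer timestamps the rule never fires, but it keeps the
computation deterministic on arbitrary logs. Top-sequence shares are
reported with all timelines starting in the layer as denominator, and the
raw count tables for every observed 2- and 3-prefix are included so any
alternative denominator convention can be recomputed from the report.

## User profiling and outcomes

Profiles are raw (untransformed) in/out degree 8-vectors; group means are
then directly interpretable as average degrees (a `log1p` transform was
considered and rejected as the default for that reason). The Gaussian
mixture uses full covariances with a 10⁻⁶ ridge on the diagonal — the
features are zero-inflated integers, and entire coordinates can be constant
within a cluster — and EM restarts 10 times by default, keeping the best
likelihood. K is chosen as the smallest value whose relative log-likelihood
gain to K+1 falls below 5%; the 5% threshold operationalizes a
plateau-versus-growth distinction (order-of-magnitude: pre-plateau gains of
tens of percent versus post-plateau gains of a few percent). If no K in the
range plateaus, the maximum K is returned with a warning flag — on strongly
heavy-tailed degree data the likelihood can keep improving throughout a
small K range, and silently pretending a plateau exists would be worse.
Selected-model groups are relabeled 1..K by descending mean total degree so
group numbering is stable across runs.

Abstinence rates are computed under intent-to-treat (ITT: nonresponders
count as smoking, denominator = group size) and responder-only conventions;
ITT ≤ responder-only holds for every group by construction. Group contrasts
use pairwise one-way ANOVA on the 0/1 indicator, which for two groups
satisfies F = t² of the pooled-variance t test (property-tested to 10⁻⁹).
No multiple-testing correction is applied to the pairwise table; the output
is descriptive and any confirmatory use should correct for the number of
contrasts. Degenerate inputs: two constant groups with equal means give
F = 0; with different means the infinite-F flag is set.

## Synthetic community generator

The generator emulates the features the analysis assumes, on an integer
event clock (only event order matters downstream, so wall-clock simulation
is deliberately avoided):

* **Roles.** A `never_visit_frac` (default 0.15) of registered users
  produce no community events at all — these populate the all-zero profile
  groups in the trial cohort. Of the visitors, `reader_only_frac` (default
  0.40) never post or message: they acquire in-ties by reading but have
  out-degree 0 in every layer, reproducing the lurker excess of zero
  out-degrees over zero in-degrees.
* **Posting.** Active users make Poisson(`activity_rate`=3) posts per public
  channel.
* **Reading.** Visitors issue Poisson(`read_rate`=6) reads per public
  channel; a read picks a post with probability ∝ (1 + the author's current
  distinct readership in that channel)^`read_attachment` (default 1). The
  weight grows with how often an author has already been read, which is the
  rich-get-richer feedback that yields heavy-tailed out-degrees; an
  attachment weight based on a quantity that readership does not increase
  would not produce the tail.
* **Welcome messages.** Each arriving visitor receives, with probability
  0.9, a private message from a small greeter pool, always read; only active
  recipients reply (probability = `coupling`). This reproduces the
  many-nodes-with-in-degree-1 PM star and keeps PM reciprocity well below
  25% under the defaults.
* **Cross-layer coupling.** After the base phases, every connected dyad
  interacts again in another public channel with probability `coupling`
  (default 0.25). Each phase draws from its own child RNG stream and every
  probabilistic decision consumes its draws unconditionally, so raising
  `coupling` under a fixed seed can only add events — the fraction of
  multi-layer pairs is provably monotone in the parameter, and the tests
  check it.
* **Outcomes.** For the first `n_trial_users` registered users (active or
  not), latent abstinence is Bernoulli with
  logit p = intercept + slope·log(1 + aggregated degree)
  (defaults −2.9 and 0.55, giving ≈ 5% abstinence for isolated users,
  ≈ 12% overall, and > 40% for the most connected — the gradient magnitude
  reported for real cessation communities); nonresponse is missing
  completely at random at rate 0.4 (matching the ≈ 42% trial nonresponse
  this kind of study reports), and nonresponders carry no abstinence report.
  True coefficients are retained on the `OutcomeTable` for recovery tests.

Defaults (500 users, 300 trial users) are chosen so a full pipeline run
takes seconds while every layer has hundreds of nodes; the acceptance script
uses 800 users / 500 trial users for slightly tighter statistics.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real data: message content and topics; wall-clock
burstiness, circadian or campaign-driven activity; user churn and re-entry;
homophily or community block structure; non-random (outcome-correlated)
survey nonresponse; and selection into the trial cohort. Results on
synthetic data validate the *computations*, not substantive claims about any
real community.

## Numerical and degenerate-input choices

* Density requires ≥ 2 nodes, reciprocity ≥ 1 edge, mean LSCC path an LSCC
  of ≥ 2 members; per-layer report generation converts these undefined cases
  to `None` rather than failing a whole run on an empty layer.
* Spearman correlations need ≥ 3 nodes in scope (`InsufficientDataError`
  below that); Jaccard is undefined when both edge sets are empty.
* All pipeline randomness (generator phases, GMM restarts) derives from one
  root seed split per stage via independent seed-sequence streams; a fixed
  configuration reproduces its report bundle byte for byte.

## Known limitations

* The plateau rule is a heuristic; with heavy-tailed raw degrees it often
  declines to plateau within small K ranges (warning flag set). Model-based
  alternatives (BIC) are deliberately out of scope to keep the selection
  rule the likelihood-plateau one.
* Mean-path sampling (very large LSCCs) introduces estimator noise that is
  flagged but not quantified.
* The ANOVA on binary outcomes is the conventional choice for this design
  but is equivalent to an unadjusted two-sample test; logistic regression
  with covariates is out of scope.
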