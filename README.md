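# ohcnet

Multirelational social-network analysis of online health community (OHC)
event logs, built around the study design used for web-based smoking
cessation communities. Members of such a community interact through four
channels — blogs (BL), message boards (MB), group discussions (GD), and
private messages (PM) — and each channel induces its own directed
subnetwork. Analyzing the four layers separately, and how ties co-evolve
across them, reveals structure (and links to smoking-abstinence outcomes)
that an aggregated network hides. The package is aimed at computational
social scientists and digital-health researchers who have timestamped
post/read logs and, optionally, trial outcome data for a subset of users.

## What it computes

**Network construction.** From a log of content creations, content accesses,
and private messages, each channel yields a directed graph where a tie
A→B means *information contributed by A reached B* (B read a post of A's, or
read a private message from A). Edges carry the first-contact timestamp;
nodes are users with degree > 0. The four layers union into an aggregated
network.

**Topology** (per layer): density `E / N(N−1)`; dyad-based reciprocity
(mutual dyads / connected dyads, where a mutual dyad has ties both ways — so
mutual = E − connected dyads); the largest strongly connected component
(LSCC) and the exact mean directed shortest-path length within it; exact
in/out/total degree histograms.

**Structural similarity**: counts of node pairs connected in exactly
k ∈ {1..4} layers (multiplexity); Spearman rank correlations ρ of per-node
in- and out-degrees between layers (union scope with zero fill by default);
Jaccard overlap |E_A ∩ E_B| / |E_A ∪ E_B| of directed edge sets.

**Coevolution**: each connected pair is reduced to its sequence of layers
ordered by pair-level first-tie time; the package reports P(layer hosts the
first tie), P(2nd tie | 1st tie in layer), P(3rd tie | 1st tie in layer), and
the top 2- and 3-tie sequences with raw counts.

**User profiling**: trial participants are represented by the 8-vector
(MB-in, MB-out, BL-in, BL-out, GD-in, GD-out, PM-in, PM-out) of layer
degrees, clustered with a full-covariance Gaussian mixture fit by EM
(best of several restarts, ridge 10⁻⁶); K is selected where the relative
log-likelihood gain to K+1 drops below a plateau threshold (default 5%).
Group abstinence rates are compared under intent-to-treat (nonresponders
count as smoking) and responder-only conventions, with pairwise one-way
ANOVA on the 0/1 abstinence indicator (F = t² of the pooled t test).

**Synthetic community generator**: since real OHC logs are proprietary, the
`synth` module simulates a community with the features the analysis assumes —
popularity-biased reading (heavy-tailed degrees), a read-only lurker cohort,
one-way welcome messages (low PM reciprocity), cross-layer dyad coupling,
and a logistic abstinence model on log(1 + aggregated degree) with survey
nonresponse. Everything downstream is testable end to end against it.

## Worked example

```python
from ohcnet import *

cfg = SynthConfig(n_users=500, n_trial_users=300, seed=42)
log = generate_event_log(cfg)
net = build_multinet(log)

rep = topology_report(net.aggregated)
print(f"aggregated: {rep.n_nodes} nodes, {rep.n_edges} edges, "
      f"density {rep.density:.2e}, reciprocity {100*rep.reciprocity:.1f}%")

pm = reciprocity(net.layer("PM"))
print(f"PM reciprocity: {100*pm.fraction:.2f}% ({pm.mutual_dyads}/{pm.connected_dyads})")

co = coevolution_report(pair_timelines(net))
print("P(first tie):", {c: f"{100*p:.1f}%" for c, p in co.p_first.items()})

out = generate_outcomes(log, cfg)
profiles = extract_profiles(net, list(out.table["user_id"]))
grouping = select_k(profiles, k_range=range(2, 7), restarts=5, seed=0)
print("selected K:", grouping.selected_k)
print(group_abstinence(grouping, out.table, "ITT").round(3))
```

prints

```
aggregated: 424 nodes, 8038 edges, density 4.48e-02, reciprocity 10.3%
PM reciprocity: 13.25% (60/453)
P(first tie): {'BL': '32.4%', 'MB': '29.8%', 'GD': '31.7%', 'PM': '6.2%'}
selected K: 6
       size  responders  abstinent   rate
group
1         3           3          2  0.667
...
6       136          76         13  0.096
```

Reading the output: the private-message layer is welcome-message dominated,
so only 13% of its connected dyads are reciprocated; first ties split mainly
across the three public channels; and the mixture model separates a small
highly connected group (67% abstinent under ITT) from a large inactive group
(10% abstinent) — the centrality–abstinence gradient the outcome model
encodes.

## Command line

```bash
ohcnet all --seed 7 --out run7            # simulate + full analysis
ohcnet simulate --seed 7 --out run7       # or stage by stage
ohcnet topology --out run7
```

Each run writes the event CSVs, per-layer edge lists (TSV), and JSON/CSV
reports (`topology.json`, `similarity.json`, `coevolution.json`,
`profile.json`, `abstinence.csv`, `anova.csv`) under the output directory.
A YAML config (`--config`) can override any generator or analysis setting.

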