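# credflow

Credibility-partitioned diffusion analysis of social-media URL sharing
around a breaking-news window.

During a disease outbreak, an "infodemic" of low-credibility content spreads
alongside legitimate public-health information. A standard surveillance
design collects a keyword-filtered tweet stream, splits it into tweets that
link *low-credibility* domains (registered domains on an independently
curated misinformation list, Iffy+-style) versus a *residual* URL dataset,
and asks how the volume, audience, propagation speed, and sharing-network
structure of each changed across the weeks before, during, and after a
breaking-news peak — and which domains and accounts drove the
low-credibility flow. `credflow` implements that full design as a tested,
reusable pipeline for epidemiologists and infodemiology researchers,
together with a synthetic stream generator that provides closed-form ground
truth, so the entire pipeline is testable as an estimator.

## What it computes

**Corpora.** Records are keyword-matched (case-insensitive, NFKC-normalized,
word-boundary for Latin scripts), URLs are collapsed to public-suffix-aware
registered domains, and each period's records are partitioned into
`low_credibility` / `residual` / `no_url` — disjoint and exhaustive.

**Temporal statistics.** Daily volume; *potential exposure* (the sum of
authors' follower counts — a readership proxy that is neither an upper nor a
lower bound of true exposure); time to first retweet with its ECDF; the
percentage of tweets retweeted within the study window; Mann-Whitney U and
Kruskal-Wallis rank tests.

**Networks.** The platform attributes every retweet directly to the original
author, so cascades flatten into broadcast (hub-and-spoke) graphs
`G = (U_w, E)`: nodes are users, a directed edge u→v with multiplicity
m(u→v) counts v's retweets of u's in-window content, and the node weight
w(u) = Σ_v m(u→v) is the total retweets u received. Degrees count distinct
neighbours, and classify each user as

    Author          k_out > 0 and k_in = 0
    Sharer          k_in > 0 and k_out = 0
    Author/Sharer   k_in > 0 and k_out > 0
    Isolate         k_in = k_out = 0

Degree centralities are k/(N−1) over the whole graph (isolates included);
eigenvector centrality is computed on the undirected, unweighted projection
by shifted power iteration. In a graph dominated by a star K₁,ₙ the maximum
eigenvector score is 1/√2 ≈ 0.707 at the hub — the signature of broadcast
structure.

**Influence.** Domains ranked by how often they are tweeted/retweeted per
period (with a popularity threshold); authors ranked by out-degree
centrality summed across periods; cohort profiles (verified share, account
age, audience size) for the userbase, authors, and top-k influential
authors.

## Worked example

```python
import credflow as cf
from credflow.simulate import SimConfig, generate_users, generate_stream, recover_parameters

config = SimConfig(seed=42)                # 2,000 users, 22 study days
users = generate_users(config)
records, truth = generate_stream(users, config)
# 60321 records (45180 tweets)

part = cf.partition_credibility(records, set(config.lowcred_pool), config.windows)
print(part.counts_table())
#       period  low_credibility  residual  no_url  total
# 0   Pre-Peak               93      2370   15354  17817
# 1       Peak               88      2946   18736  21770
# 2  Post-Peak               58      2917   17759  20734

est = recover_parameters(records, config.windows, set(config.lowcred_pool))
mult, se = est["peak_multiplier"]          # 2.48 +/- 0.08   (truth 2.5)
frac, _ = est["retweeted_fraction"]        # 15.4%           (expected 15.3%)
```

The on-topic posting rate rises inside the Peak window (the totals above:
~17.8k → 21.8k records) and the pipeline recovers the planted 2.5× shock as
2.48 ± 0.08. The peak-window low-credibility network shows the broadcast
signature:

```python
from credflow.network import build_graph, analyze_graph
G = build_graph(part.records(period="Peak", cls=cf.CredClass.LOW_CREDIBILITY))
print(analyze_graph(G).centrality_stats)
#        measure    median   maximum
# 0    in_degree  0.011765  0.011765
# 1   out_degree  0.000000  0.588235
# 2  eigenvector  0.100000  0.707106
```

The out-degree median is exactly 0 (sharer-dominated network) and the
maximum eigenvector score is 1/√2 (a dominant star component).

## Command line

```sh
credflow demo --out demo_run --seed 0          # simulate + analyze
credflow simulate --out sim --seed 0           # stream + ground truth only
credflow analyze --config pipeline.yaml        # analyze your own stream
```

`analyze` reads a YAML config naming the JSON-Lines stream, the
low-credibility domain list, keyword lists, period windows, and thresholds;
it writes the full report bundle (corpus summary, exposure, retweeted
fractions, latency quantiles, compositions, centrality summaries, domain
rankings, top-k authors, account profiles) as CSV/JSON plus a run manifest.
The JSON-Lines schema is documented in `credflow/records.py`.

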