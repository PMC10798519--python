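# Methods

## The analysis model

`credflow` analyses a keyword-collected stream of tweet records around a
breaking-news window split into three labelled periods (default: the weeks
before, during, and after the March 2021 peak of news coverage linking the
Oxford/AstraZeneca COVID-19 vaccine to rare blood clots: 4–10, 11–17, and
18–25 March 2021, end dates inclusive, assignment by UTC calendar date).
Low-credibility content is proxied by URL domain: a record is
low-credibility iff at least one of its URLs resolves to a registered
domain on a curated misinformation domain list. This proxy underestimates
misinformation (it sees only linked content, and only listed domains); the
pipeline inherits that limitation by design.

### Domain matching

Matching is at the registered-domain (public-suffix-aware) level, so
subdomains of a listed domain count as listed; list entries are themselves
registrable domains, so finer matching would silently miss subdomain
links. The extractor strips scheme, credentials, port, path, query,
fragment, and a leading `www.`, then takes the label left of the public
suffix. A curated table of common multi-part country-code suffixes
(`co.uk`, `com.au`, …) covers three-label registrations; unknown suffixes
fall back to the final two labels. Unparseable URLs map to the sentinel
`invalid`: they never match the list but the record still counts as
URL-containing. A record with several URLs is low-credibility if any one
matches (one reference suffices).

### Keyword matching

Case-insensitive after NFKC normalization and casefolding. Latin-script
keywords match on word boundaries — `vaccine` does not hit `vaccinate`,
but a standalone `ICU` token matches even in off-topic celebrity chatter,
reproducing the known false-positive mode of broad keyword collection.
Keywords in non-spaced scripts (CJK, Thai, …) match as raw substrings.
Each record is matched on its own text; retweets carry the source text, so
they inherit topical membership naturally.

### Temporal statistics

*Potential exposure* sums the author's follower count per record — every
record, retweets included, since a retweet is a post by its retweeter; a
flag restricts to originals. The per-record mean and sample SD (ddof = 1)
are printed at two significant figures. *Time to first retweet* is the
minutes from an original to its earliest observed retweet; originals with
no observed retweet contribute no latency but count in the retweeted
fraction's denominator. Retweets stamped before their source are rejected
with a data-integrity warning. The *retweeted fraction* counts originals
with at least one retweet inside the study window, printed at three
significant figures. Rank tests (two-sided, tie-corrected Mann-Whitney U
and Kruskal-Wallis) delegate to scipy; identical all-tied samples return
(0, 1) rather than scipy's refusal.

### Networks

Within one (period, credibility-class) record set, an edge author→retweeter
is created only when the retweeted tweet itself is present in the same set
and window; retweeters of absent content (posted before the window, or
outside the class) remain isolates, and self-retweets are dropped and
counted. Degrees count distinct neighbours, not multiplicities, matching
the definition of in-degree as the number of different authors retweeted.
Degree centralities normalize by N−1 with N the whole node set including
isolates — this is why sharer-dominated broadcast networks have out-degree
median exactly 0 and tiny in-degree medians.

Eigenvector centrality is computed on the undirected, unweighted
projection (multiplicity ignored) by power iteration on **A + I** from a
uniform start, stopping when the maximum absolute change drops below 1e−6
(cap 1,000 iterations; exceeding the cap raises, naming the cap). The
identity shift preserves eigenvectors while making the dominant eigenvalue
strictly largest in magnitude; plain power iteration oscillates on
bipartite graphs, and the star K₁,ₙ — the very shape these broadcast
networks take — is bipartite. The result is L2-normalized and nonnegative;
on disconnected graphs the dominant component carries the mass and other
components score numerically ~0, so near-zero scores off the main hub are
expected, not an error. For a lone star the hub scores exactly 1/√2 and
each leaf 1/(2n)^½, which is why star-dominated networks report maximum
eigenvector scores near 0.71.

Medians and maxima are taken over all nodes, isolates included.

### Influence

Domain popularity counts each record (tweet or retweet) once per distinct
domain it references, per period; a domain is retained iff it reaches the
threshold in at least one period, and rows sort by total count with
lexicographic tie-break. Author influence sums out-degree centrality
across the period graphs (absent periods contribute 0; this uses the
normalized centralities as stated, with raw distinct-retweeter counts
available in the node tables for sensitivity); ties break by total
retweets received, then user id, so rankings are deterministic and
order-invariant. Account profiles report verified share (two significant
figures), yearly account-creation histograms with a share-since-cutoff
(default cutoff 2020-03-11, the WHO pandemic declaration), and follower
medians with log-decade histograms; the "authors" cohort includes
Author/Sharers by default (a strict-authors flag excludes them).

## The synthetic generator

The study's raw stream is not redistributable, so the generator emulates
the features the analysis depends on, with defaults chosen to mirror the
study's published marginal statistics:

| parameter | default | rationale |
| --- | --- | --- |
| `n_users` | 2,000 | desk scale: ~60k records, ~1 s generation |
| `follower_mu`, `follower_sigma` | ln 200, 2.0 | heavy-tailed audiences, userbase median ≈ 200 followers |
| `verified_base_prob` (+ boost) | 0.008 (+0.10/decade > 10⁴) | sub-1% verified userbase, verification concentrated in large accounts |
| `creation_spike_weight` | 0.25 | 25% of accounts created since 2020-03-11 (pandemic-era spike) |
| `base_rate` | 1 tweet/user/day | Poisson posting |
| `topic_share` | 0.05 | on-topic sub-corpus large enough for period-level estimates at this scale |
| `peak_multiplier` | 2.5 | on-topic volume roughly doubling-to-tripling inside the peak |
| `p_url` | 0.145 | URL share of the stream |
| `p_lc_base`, `p_lc_peak` | 0.019, 0.029 | low-credibility share of URL tweets off-peak / on-topic-in-peak |
| `retweet_rate_scale`, exponent | 0.04, 0.25 | E[retweets] ∝ followers^0.25; implies ~15% retweeted fraction |
| `delay_log_mu`, `delay_log_sigma` | ln 10, 2.0 | lognormal first-retweet delays, median 10 min |
| hub (`hub_*`) | 5M followers, 5× rate, 25× retweet boost | a dominant corporate outlet account |

All randomness flows through one seeded `numpy` generator per stage
(users: `seed`; stream: `seed + 1`), so runs are byte-deterministic.

Cascades are *flattened by construction*: the generator attributes every
retweet directly to the original author and never creates intermediary
chains, because the data model cannot represent them — a deliberate
fidelity-to-limitation choice. Retweet counts per tweet are Poisson with
intensity λ_u = scale·(1+followers_u)^γ; delays are lognormal; retweets
falling past the window end are censored exactly as a fixed collection
window would censor them. One planted low-credibility outlet domain holds
40% of the low-credibility pool weight, and the planted hub account — the
corporate account of that outlet — posts only on-topic at an elevated
rate, follows the same peak shock, and links its *own* outlet domain
whenever it posts a low-credibility URL (outlets self-promote; the
coupling of a dominant domain to its corporate account is the structure
the influence rankings are designed to find).

`expected_statistics` returns closed-form expectations: period volumes as
rate sums; low-credibility shares as the configured probabilities per
regime; and the retweeted fraction as the rate-weighted average of
1 − exp(−λ_u·F(T_end − t)) with F the delay CDF, integrated over posting
times with a four-point per-day quadrature — i.e. it accounts for
end-of-window censoring. `recover_parameters` re-estimates the peak
multiplier (per-day on-topic count ratio), the two low-credibility shares
(binomial, among URL-carrying originals per regime), and the retweeted
fraction, each with a delta-method or binomial standard error, using only
pipeline operations.

### What passing tests do and do not show

The generator has no circadian cycles, no follower-graph topology, no
reply/quote structure, no bot behaviour, and no language mixture; texts
are templated. Passing the recovery suite therefore shows that the
pipeline is a correct and unbiased estimator *under the stated generative
laws*, not that those laws exhaust real platform behaviour. Conversely,
the printed-table arithmetic checks exercise only the summary operations,
not collection.

## Numerical and reporting conventions

* All printed percentages round half-up (`decimal`-based, not banker's
  rounding). Corpus/URL share percentages print at one decimal;
  low-credibility shares at two significant figures; composition shares at
  one decimal in tables and three significant figures in running text;
  retweeted fractions at three significant figures. One published
  composition entry (80.9% for 26,448/32,713 = 80.85%) is unreachable
  under any standard rounding and is treated as a typo; the code prints
  80.8 for those counts. Reports always carry the unrounded value next to
  the printed one.
* Zero denominators yield NaN ("undefined"), never 0.
* Eigenvector power iteration: uniform start, tol 1e−6 (max absolute
  change), cap 1,000; tests that compare against a dense eigensolver
  tighten tol rather than loosening the 1e−5 comparison.
* Graph exports and all report tables are sorted, so outputs are
  independent of input record order; a fixed seed reproduces the whole
  report bundle checksum-identically.

## Problem sizes

Tests and the acceptance script run the generator at its default scale
(2,000 users, 22 days, ≈60k records, ≈1 s per replicate); the recovery
acceptance uses 20 seeded replicates with a 3-standard-error criterion per
parameter and a 19/20 pass requirement, and the small-graph eigenvector
checks run exhaustively over the connected-graph atlas up to 7 nodes plus
seeded 12-node random graphs.

## Known limitations

* The curated public-suffix table is not the full PSL; exotic suffixes
  fall back to two-label registration.
* Eigenvector centrality on graphs whose top two eigenvalues are nearly
  (but not exactly) tied converges slowly; the iteration cap then raises
  rather than returning an inaccurate vector.
* Retweet observability is truncated by the collection window; fractions
  and latencies are therefore window-conditional quantities, matching the
  "retweeted within the study period" definition rather than an
  uncensored propensity.
* First sighting wins in user tables: if an account's metadata changed
  mid-window, the earliest record's values are used.
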