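# orna — organizational network analysis of HIV and family-planning referral networks

`orna` audits how the organizations serving women living with HIV in a
catchment area — government hospitals, health centers and posts, NGOs,
faith-based organizations (FBOs), private clinics — refer clients to one
another, and where that referral web leaves needs unmet. It implements the
full analysis pipeline for a two-sub-city study in Addis Ababa, Ethiopia
(Kirkos and Kolfe Keranyo): roster construction from snowball nominations,
directed-network description, exponential-random-graph (ERGM) homophily
probing, service-gap detection, and the workshop handouts used to feed the
results back to the organizations. The raw sociometric data were never
published, so the package ships a synthetic-data generator whose two
networks reproduce every printed marginal of the study.

It is aimed at epidemiologists and health-systems researchers running
organizational network analyses of service integration.

## The statistics at its core

For a directed simple graph with $n$ organizations and $m$ referral arcs:

- **density** $= m / n(n-1)$;
- **dyad census** $(M, A, N)$: mutual, asymmetric and null unordered
  pairs, with $M + A + N = \binom{n}{2}$ and $m = 2M + A$;
- **reciprocity** (dyadic) $= (M + N)/(M + A + N)$, the share of
  *symmetric* dyads — the convention that reproduces the study's printed
  values; arc reciprocity $2M/m$ is also exposed;
- **Freeman centralization** $= \sum_i (c_{\max} - c_i) / (n-1)^2$ for in-
  or out-degree;
- **ERGM** $P(G) \propto \exp(\theta \cdot s(G))$ with dyadic-independent
  terms (edges, nodematch, nodemix, absdiff, sender/receiver covariates,
  edge covariates), fitted by maximum pseudolikelihood — a Newton logistic
  regression of the arc indicator on the change statistics
  $\delta(i,j) = s(G + ij) - s(G - ij)$, which for these terms is the exact
  MLE — and simulated by a single-arc-toggle Metropolis chain;
- **service gap**: an organization that neither provides a service domain
  (family planning, or the HIV service array) nor refers clients to any
  organization that does.

## Worked example

```python
from orna import make_paper_fixture, summarize
from orna import ergm, gaps

kirkos = make_paper_fixture("kirkos")
print(summarize(kirkos).as_display_row())
fit = ergm.fit_mple(kirkos, [ergm.edges(), ergm.nodematch("org_type")])
print(dict(zip(fit.terms, fit.coef.round(3))))
print(gaps.flagged_orgs(gaps.detect_gaps(kirkos), domain="FP"))
```

prints

```
{'subcity': 'Kirkos', 'links': 69, 'density': 0.115, 'centralization': 0.184,
 'out_degree': 2.76, 'in_degree': 2.76, 'reciprocity': 0.83}
{'edges': np.float64(-2.386), 'nodematch.org_type': np.float64(0.788)}
['K16', 'K17']
```

The Kirkos network has 25 organizations and 69 referral arcs, a density of
0.115 (11.5% of possible ordered referral links exist) and dyadic
reciprocity 0.83. The positive `nodematch.org_type` coefficient says
organizations preferentially refer to their own type (driven by a clique of
four FBOs referring to one another). Two HIV-only organizations refer
clients to no family-planning provider — the two service gaps the audit
exists to find.

The numbered scripts under `analysis/` run the complete study: generating
both sub-city networks (`01`), recovering the rosters from nomination data
(`02`), the relational-characteristics table and mixing matrices (`03`),
the ERGM homophily report (`04`), the gap audit and referral grids (`05`)
and the workshop directory/complementary-services handouts (`06`). Each
writes its tables under `results/`.

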