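# Methods

This note documents the model equations, the default parameters and why they
were chosen, the behavioral closure rules where the published theory leaves
the form open, and the limits of what the synthetic experiments can show.

## Landscape

The world is a rectangular grid of 1-ha cells (default 100 × 100; experiments
and tests use 20 × 20 for speed — results reported by the acceptance script
state their problem sizes). Terrain is smoothed Gaussian noise with
correlation length ≈ 3 cells; elevation is expressed in cell-width units so
percent slope is 100 × the central-difference gradient magnitude. The default
`roughness` of 0.25 puts the median cell around the 5–16% slope class, giving
a realistic mix of prime and marginal land; `roughness=0` yields a flat,
homogeneous landscape.

Slope suitability is a piecewise-constant GAEZ-style class table
(≤2% → 1.00, 2–5 → 0.90, 5–8 → 0.75, 8–16 → 0.50, 16–30 → 0.25,
>30 → 0.05), configurable because published class boundaries vary. The
precipitation constraint is a flat 50% yield reduction. Constraints compose
multiplicatively with each other and with the cell's degradation state —
standard agro-ecological zoning practice.

Per-cell dynamics: cultivation of extensive agriculture (grazing of pasture)
reduces the yield state by 0.25 (0.18) per year; fallowed cells regenerate at
the rate of their most recent productive use (0.04 extensive, 0.5 pasture)
and succeed to forest after 10 fallow years (succession is named in the
source literature without a rate; 10 years is a typical secondary-succession
time scale). Degradation and regeneration rates are read as fractions of
pristine yield potential per year. **Intensive agriculture is the exception
on both sides**: it neither degrades nor inherits prior degradation — by
definition it uses external inputs (fertilizer, irrigation, land improvement)
to maintain full productivity. This matters structurally: if intensive yields
scaled with the degradation state, extensive cultivation would dominate it in
kg per person-week on every cell at every state and intensification could
never occur.

Labor costs (person-weeks ha⁻¹ yr⁻¹) are relative, not calibrated to any
particular system: maintenance 10 / 6 / 5 for intensive / extensive /
pasture, plus conversion adders (+4 clearing forest, +2 breaking fallow, +1
between productive uses). Pasture's 5 pw ha⁻¹ keeps extensive cropping the
dominant staple channel (2700/6 > 1700/5 kg per person-week), reflecting that
its grain-equivalent output is fodder and livestock, not staple food.

## Market

A single global market-influence index MI ∈ [0, 1] is mapped to local
conditions by five linear functions (the published account fixes only the
endpoints — global commodity price and U.S. minimum wage at MI ≈ 1 — and the
monotone direction; linear forms keep the calibration genome small):

| quantity | form | default coefficients |
|---|---|---|
| farm-gate price | `p·(b_f + (1−b_f)·MI)` | p = 0.13 \$/kg, b_f = 0.3 |
| food price | `p·(1 + m_w(1−MI))` | m_w = 1.0 |
| input cost | `c_0(1 + c_1(1−MI))` | c_0 = 100 \$/ha, c_1 = 1.0 |
| non-farm wage | `w_max·MI` | w_max = 290 \$/pw (7.25 \$/h × 40 h) |
| transaction cost | `τ_0(1−MI)` | τ_0 = 19,000 \$/household-yr |

The transaction cost represents the annual overhead of locating, securing,
and maintaining non-farm employment; it is charged per household engaged
(fraction = non-farm weeks / 96) and amortized per person-week when the
agent values wage work (`w_net = max(0, w − τ/96)`). τ_0's default is large
by design: it is the participation threshold that makes wage labor
uneconomic in poorly connected settlements. With the defaults, `w_net` is
zero below MI ≈ 0.39, overtakes the returns to market cropping near MI 0.5,
and approaches the full wage as MI → 1 — placing the three livelihood
transitions at the MI boundaries where the source study observed them. The
coefficient vector (b_f, m_w, c_0, c_1, τ_0) is the genome searched by the
calibration GA, so the defaults are a starting point, not an assertion.

## Agents

One agent per contiguous 100-ha settlement block; households within a
settlement are identical (4 people, 3 adult-equivalent consumers, 96
person-weeks yr⁻¹, δ_min = 860 kg per adult-equivalent, initial stocks
2,580 kg and 1,426 \$ per household). `consumers_per_household = 3` makes the
printed initial food stock internally consistent (2,580 = 3 × 860).
Fractional households are allowed so density is a continuous dial. Risk
preference R_pref is drawn once per agent from Uniform(0, 1) on a
seed-derived stream.

Expectations are backward-looking: with observations (x_{t−1}, x_t) the
forecast is `2x_t − x_{t−1}`, clamped at zero; a single observation forecasts
itself. Risk enters through the certainty equivalent `CE = μ − R_pref·σ`,
floored at zero. Yield expectations track a multiplicative "yield factor"
(realized over potential), so degradation and environmental constraints enter
through potential yields and noise through the factor.

The shadow price is the minimum over the agent's cells and staple uses of
`(input cost + labor cost × w_net) / CE yield` — the cost of self-provisioning
one kilogram. Its position relative to the farm-gate and food prices selects
the regime: below the farm-gate price, market production is profitable
(mixed); between the two prices, the agent is in the autarkic price gap
(subsistence); above the food price, buying food and selling labor dominates
(sell-and-buy). Boundaries resolve toward the more subsistence-oriented
regime.

### Annual labor allocation (satisficing closure)

Smallholder theory says labor and risk are minimized, not profit maximized;
aspirations rise with market integration. The allocation therefore works
through targets:

1. **Food target** = annual need + (one-year stock reserve − current stock),
   floored at zero. In the sell-and-buy regime a share of it equal to MI is
   planned as purchases (market food availability ramps with integration);
   the rest is produced.
2. **Subsistence fill**: owned cells are ranked by CE yield per
   labor-equivalent person-week and taken greedily until expected CE
   production covers the target; the marginal cell is cultivated
   fractionally. Monetary input costs are converted to labor-equivalents at
   the best available cash-earning rate (net wage or best market-crop margin
   per person-week), so intensive cultivation is adopted exactly when land
   becomes scarce enough that its full, degradation-free yield beats worn
   extensive plots.
3. **Cash target** = required spending (inputs, planned food purchases) plus
   an aspiration `A = n_households × 1,426 × MI⁴`, plus replenishment of a
   cash reserve. The quartic ramp implements "aspirations transform with
   market integration": negligible in isolated settlements, approaching a
   year's cash needs per household as MI → 1. (The exponent is the smallest
   integer for which non-farm engagement is monotone in MI on the analytic
   toy fixture; cubic aspirations produce a dip between MI 0.65 and 0.8
   where the target grows more slowly than the net wage.)
4. **Earning fill**: market-crop cells (ranked by \$ per person-week, net of
   inputs) compete with non-farm weeks at `w_net`; the better channel is
   taken until the cash target is covered or labor runs out. Remaining labor
   stays home — this is what keeps farm-labor shares near 100% at low MI
   even though some wage might nominally be positive.
5. **Damping**: each activity's labor may move per year by at most
   `λ × total labor`, `λ = clip(λ_0·|ΔS|/S_target, λ_min, λ_0)` with
   λ_0 = 0.5 and λ_min = 0.05, where ΔS is the last year's change in the
   relevant stock (food for subsistence labor, money for market and wage
   labor). The floor keeps agents able to track slow degradation-driven
   drift even when stocks are stable.

Ties everywhere break toward the lowest cell index, then the land-use enum
order. An agent with a positive production target, no viable option, no
stocks, and no purchase channel is flagged failed and idles for the year.

### Stocks

Food: `stock += production − consumption − sales + purchases`. Consumption is
the subsistence requirement capped by availability (shortfalls logged). When
the post-consumption stock exceeds the one-year reserve, households consume
part of the excess (up to 50% of the annual requirement) — richer diets,
feed, and festivals. This surplus consumption is the sink that lets the
risk-planning margin appear as a *normal surplus* (mean production ≈ 1.05–1.1
× requirement) instead of being absorbed by the stock-feedback loop, which
would otherwise pin production to exactly the requirement.

Money: `stock += sales·p_f + wages − purchases·p_c − inputs − transaction
costs − aspiration spending`, floored at zero with overdrafts logged.
Aspiration spending (consumption of market goods) is capped so it never draws
the stock below the settlement's reserve (1,426 \$ per household). Purchases
are capped by available cash. Both balances are exact identities, asserted at
every agent-year by the test-suite.

## Engine

Annual loop: expectations → allocation (all agents) → yield realization →
trade and stock updates → landscape update → recording. Yield noise is
multiplicative lognormal with mean 1 and CV 0.10 per cell-year (risk
preferences are behaviorally inert without stochastic yields); terrain,
R_pref draws, and yield noise use sub-streams split deterministically from
the run seed, so a configuration and seed reproduce results bit-for-bit.
Runs are 20 years with the first 10 as spin-up; all reported metrics use the
post-spin-up window.

## Calibration and experiments

Pattern thresholds default to: surplus ratio ∈ [1.0, 1.5], cash needs covered
in ≥ 90% of post-spin-up years (cash need = that year's realized inputs +
purchases + transaction costs), consumption-smoothing CV ≤ 0.2 where
`D_t = (production_t + income_t / food price) / requirement`. The GA is a
plain generational algorithm (population 32, tournament 3, blend crossover
0.7, bounded Gaussian mutation with sd 10% of range) with fitness = patterns
passed − normalized distance of failing metrics (pure pass/fail is flat
almost everywhere). One simulation per genome with a fixed evaluation seed
keeps the search well-posed; every successful genome is archived and each
archived genome re-simulates successfully by construction.

The factorial laboratory enumerates densities {16, 48, 80, 112, 144} ×
MI {0.20, 0.35, 0.50, 0.65, 0.80} × the four landscapes = 100 settings.
Cropping frequency counts intensive and extensive cultivation only (pasture
is grazing, not cropping); run-level summaries report both the area-mean
frequency (the intensity of the whole landscape) and the median per-cell
value. Transitions are detected on jointly ranked run metrics with Scheffé S
half-widths `sqrt((k−1)·F_{α;k−1,N−k}) × SE` from the rank-ANOVA mean square
error; a 99% interval excluding zero flags a shift, labeled by the direction
of the median change.

Where a test or the acceptance script needs a single setting on the MI axis
(low-MI subsistence dominance, transition directions, GA calibration), it
uses the neutral landscape at density 64: the unconstrained landscape
isolates market effects from environmental mediation, which the density- and
landscape-axis checks cover separately on the constrained landscapes. The
environmental-mediation check compares the precipitation-constrained and
neutral landscapes at MI 0.2, where production is autarkic and the constraint
translates directly into cultivated area.

## What the synthetic experiments do and do not show

The landscape, prices, and labor costs are stylized; passing tests show that
the decision mechanisms generate the qualitative regularities of
induced-intensification and livelihoods theory (intensity rising with
density, exacerbated by environmental constraints; normal surplus; the
market-driven transition sequence), not that the model is calibrated to any
real land system. Numerical outcomes depend on the cost/price genome, which
is exactly why calibration archives *sets* of plausible genomes rather than
a point estimate. Known limitations: single cropping only (no multi- or
inter-cropping, so intensity saturates at 100% cropping frequency), no
inter-agent interaction, land tenure, demography, or migration; a single
global MI per run; intensive cultivation never degrades regardless of input
price, and food markets at low MI are simply absent rather than thin.
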