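# duosync

Cross-wavelet analysis of interpersonal coordination in music-duo motion
capture.

When two musicians perform together — here a "Lied" duo, a singer
carrying the melody with a pianist accompanying — their body sway
carries shared periodicities tied to the musical phrase structure, and a
consistent phase offset between the two reveals who leads and who
follows.  `duosync` turns score beat onsets and 3-D marker trajectories
into those quantities, for movement scientists and music-performance
researchers who want a tested, scriptable version of this analysis (and
a synthetic-data generator to validate it end to end).

## The method in brief

- **Tempo scale.** The mean inter-beat interval (IBI) of a performance
  converts phrase levels (½, 1, 2, 3, 4 bars) into durations in seconds:
  `duration = mean IBI × beats-per-bar × bars`.
- **Signal.** Marker speed `‖v‖₂` from a Savitzky–Golay velocity filter
  (order 3, window 25) of the front-head marker of each performer.
- **Cross-wavelet transform.** With Morlet wavelet ψ (ω₀ = 6), the
  cross-spectrum of the pianist's and singer's speed series is
  `Wxy(s, t) = Wx(s, t) · conj(Wy(s, t))`.  Coordination strength is the
  power `|Wxy|`; the phase difference `φ = arg(Wxy) ∈ (−π, π]` encodes
  leadership: φ > 0 in the in-phase regime means the pianist's
  oscillation is earlier in the cycle.  Band means over tempo-scaled
  narrow bands (duration × 2^±0.25, clipped to non-overlap) use a
  circular mean for φ, converted to milliseconds via
  `ms = φ/(2π) × duration × 1000`.
- **Statistics.** Mixed-effects models (REML, random intercept per duo,
  automatic OLS fallback when the between-duo variance is negligible)
  for power/phase by phrase level and take; linear models for the
  empathy covariates (EPT, the Interpersonal Reactivity Index
  perspective-taking score of each musician); Tukey post-hoc contrasts;
  Bonferroni-corrected threshold 0.05/24 = 0.002083 for the empathy
  battery.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

A one-command synthetic run — 4 duos, a shared two-bar oscillation
planted in both performers' head speed with a singer-lead lag of
10 ms per unit of singer EPT above the cohort midrange:

```sh
$ cat run.yaml
seed: 7
piece: schumann
n_duos: 4
n_bars: 40
fs: 20.0
noise_sd: 2.0
lead_slope: 0.01
out_dir: results

$ duosync run --config run.yaml
analyzed 4 sessions; results in results (dominant levels: {'two': 4})
```

`results/dominant.csv` then contains, per duo, the dominant phrase
level, its band-mean cross-wavelet power, and the band-mean phase in ms:

```
duo_id  singer_ept dominant_level  mean_power  phase_ms    leadership
 duo00          25            two     2184.37    -46.57  singer_leads
 duo01          14            two     2154.50     66.89 pianist_leads
 duo02          24            two     2139.02    -34.11  singer_leads
 duo03          19            two     2124.44     10.85 pianist_leads
```

Every duo recovers the planted two-bar dominant level, and the sign of
`phase_ms` tracks the planted leadership: high-EPT singers (25, 24) lead
(negative phase), low-EPT singers lag (positive phase), with magnitudes
close to the planted `10 ms × (EPT − 20.5)`.  `results/` also holds the
per-band aggregate table, peak-occurrence percentages by phrase level,
per-section (solo vs together) aggregates, model summaries, the planted
ground truth, and a JSON run-metadata sidecar (config, seed, version).

Each stage is also available separately (`duosync simulate / tempo /
kinematics / xwt / coordinate / stats`) on shared on-disk intermediates,
and as library functions under `duosync.*`.

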