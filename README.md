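# gibmove

Movement-ecology analysis of single-individual GPS/Argos telemetry,
built around the tracking study design used for the critically
endangered Great Indian Bustard (*Ardeotis nigriceps*) in the semi-arid
Deccan landscape: a solar PTT recording seven GPS fixes per day on a
fixed 05:30–19:30 schedule over roughly 410 days.

The package answers four questions about such a trajectory:

1. **How does the bird move?** Step lengths (geodesic distances between
   successive fixes) are fitted with a continuous power law
   `p(x) ∝ x^(−μ)` above a lower cutoff `x_min` by maximum likelihood
   (`μ̂ = 1 + n / Σ ln(x_i/x_min)`, cutoff chosen by KS-distance scan).
   Exponents `1 < μ < 3` indicate Lévy-flight search behaviour; values
   near 3 approach Brownian-like diffusion. Fits are produced overall
   and per season (summer Mar–Jun, monsoon Jul–Sep, post-monsoon
   Oct–Nov, winter Dec–Feb), together with daily/seasonal displacement
   summaries, hourly movement rates, turning-angle histograms (mean
   resultant length R̄) and powerline-crossing counts.
2. **Where does it live?** Kernel-density utilization distributions
   (bivariate Gaussian kernel, reference bandwidth
   `h = n^(−1/6)·√((s²_x+s²_y)/2)`) with 50% (core) and 95% (range)
   isopleths, their areas and connected components, and month-to-month
   UD overlap (area-Jaccard of the 95% isopleths by default; volume of
   intersection and Bhattacharyya affinity also implemented).
3. **Where does it linger?** Sequential spatio-temporal clustering:
   a chronological pass in which each fix joins the nearest open
   cluster whose running centroid is within a search radius (default
   2702 m) and whose last admission is within a temporal window
   (default 4 days), with a minimum of 28 member fixes.
4. **What is there?** Per-cluster habitat configuration: land-cover
   percentages, road density (km/km²), distance to the nearest
   powerline, and mean NDVI from the dated layer nearest the cluster's
   start date.

A synthetic-data module generates trajectories with exactly the
statistical structure the analysis assumes (seasonal truncated-Pareto
steps, uniform headings, stationary multi-day phases) plus a synthetic
landscape (categorical land cover, NDVI fields, powerlines and roads),
so the entire pipeline runs and is tested without any telemetry
download. Geodesic distances use Vincenty's method on the WGS84
ellipsoid; the metric working CRS is UTM 43N (EPSG:32643).

## Worked example

Simulate a study-length trajectory and analyse it end to end:

```sh
gibmove simulate --seed 42 --start 2015-04-15 --end 2016-05-28 \
    --with-landscape -o demo
gibmove analyze demo/fixes.csv --landscape-dir demo/landscape -o demo_out
```

which prints

```json
{
  "total_distance_km": 1896.8618948474937,
  "overall_mu": 2.147125071704095,
  "n_clusters": 33
}
```

`demo_out/report.json` holds the full report. For this seed the
simulated bird moved 0.267 km/h on average (4.63 km/day, maximum day
42.2 km); the overall exponent μ̂ = 2.15 is classified `levy`, and the
per-season fits recover the generator's seasonal exponents (summer
2.42 vs 2.44 simulated, monsoon 2.25 vs 2.20, post-monsoon 2.87 vs
2.89, winter 1.91 vs 1.74). The turning-angle mean resultant length is
0.022 — no directional persistence, as expected from uniform headings.
The 50% core area is 2784 km² in 2 components and the 95% range
11,933 km²; consecutive-month 95%-isopleth overlaps are written to
`demo_out/monthly_overlap.csv`. Stage outputs (`steps.csv`,
`daily.csv`, `clusters.csv`, `habitat.csv`, `ud_density.asc`,
`cluster_footprints.geojson`) are all plain text.

Real telemetry goes through the same commands: a CSV with
`animal_id,timestamp,lon,lat,source` columns (ISO-8601 timestamps;
naive times are read as UTC+05:30; other column names can be remapped).

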