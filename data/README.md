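# Fingerprint database tables

The full-leaf and fragment venation-fingerprint databases (186 leaves and
leaflets, with in-silico 1.2 × 1.2 cm fragments) are not redistributed
with this package. To run the database-dependent acceptance tests, place
CSV conversions of the tables here:

- `s1_leaf_fingerprints.csv` — one row per leaf/leaflet
- `s2_fragment_fingerprints.csv` — one row per fragment

Expected columns in both files:

```
specimen_id,species,sigma,a,A,rho_A,d,L_top,i_u,i_w
```

ODS spreadsheets can be loaded directly by
`veintop.load_fingerprint_table` when an `odfpy`-backed pandas engine is
installed; otherwise convert to CSV with the same column names.
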