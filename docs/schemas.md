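# File schemas

All tabular files are UTF-8, comma-delimited, with a header row.
Reports and ground truth are JSON.  Blank cells mean "absent" for
optional fields and 0 for counts.  The constants in
`hotspot_mapper.io` (`GEOGRAPHY_COLUMNS`, `MENTION_COLUMNS`,
`LEVEL_TWO_COLUMNS`, `REGISTER_COLUMNS`) mirror this document.

## geography.csv

| column | type | notes |
|---|---|---|
| `id` | string | unique |
| `name` | string | |
| `level` | `county` / `subcounty` / `zone` | strict 3-tier tree |
| `parent_id` | string | blank for counties only |
| `female_pop_14_24` | int ≥ 0 | AGYW denominator (persons); required > 0 at county level |
| `female_pop_14_44` | int ≥ 0 | reproductive-age denominator; required > 0 at county level |

## mentions.csv (level-one reports)

| column | type | notes |
|---|---|---|
| `raw_name` | string, nonempty | as reported by the informant |
| `zone_id` | string | must exist in geography |
| `informant_type` | string | free text (e.g. `taxi_driver`) |
| `typology_guess` | typology code or blank | see codes below |
| `mention_date` | ISO date or blank | |

## level_two.csv (on-site validation records)

One row per visited venue (duplicate `hotspot_id` is an error).

| column | type | notes |
|---|---|---|
| `hotspot_id` | string | venue identifier; linked to the register by id or name+zone |
| `hotspot_name` | string | proper venue name recorded on site |
| `zone_id` | string | |
| `typology` | typology code or blank | assigned during validation |
| `active` | `true`/`false` | validation outcome |
| `peak_day_of_week`, `peak_time` | string | |
| `<group>_<day>_min`, `<group>_<day>_max` | int ≥ 0 | 16 columns: groups `fsw_all`, `fsw_14_24`, `transactional_14_24`, `casual_14_24` × days `normal`, `peak`; min ≤ max; `fsw_14_24` ≤ `fsw_all` per day/bound |
| `men_min`, `men_max` | int or blank | stored, never analysed |
| `mobility_responses` | `;`-joined ints ≥ 1 | venues visited per respondent, index venue included (1 = not mobile) |
| `snowball_mentions` | `\|`-joined strings | venue names referred by respondents |

## register.csv / program_listing.csv

| column | type | notes |
|---|---|---|
| `id` | string | unique |
| `canonical_name` | string | most frequent raw spelling of the cluster |
| `zone_id` | string | |
| `typology` | typology code or blank | blank only while status is `named` |
| `status` | `named` / `validated_active` / `inactive` | |
| `known_to_program` | `true`/`false` | |
| `source` | `level_one` / `level_two_snowball` / `program_listing` | |

## Typology codes

`public_place`, `street`, `bar_nightclub_casino_hotel`,
`bar_restaurant_cafe`, `guesthouse_lodge`, `sex_den_brothel`,
`local_brew_den`, `other`.

## groundtruth.json

Written by the synthetic generator: the generator config, per-venue
truth (zone, typology, activity, program flag, overlap category, true
attendance per group/day), distinct-individual population per
geography and group, true mobility (p, m) per subcounty, the respondent
pool per venue, and the mentioned/reachable venue id lists.

## report.json

Written by `run_pipeline` / `hotspot-mapper run`: resolved
configuration, the conventions in force, register accounting, mobility
parameters, estimates per group × geography (crude and adjusted, raw
and reported), overlap summary, typology table with chi-square, and
the known/new split.  Keys are sorted; reruns are byte-identical.
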