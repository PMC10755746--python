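# Region scheme for the three-region rove-beetle barcode audit.
#
# A record's collection country resolves to at most one region.  Bare
# "Russia" resolves to no region: both West Siberia and the north-western
# (Fennoscandian) part of Russia are sub-country areas, representable only
# through admin-unit overrides, and attributing an unqualified Russian
# record to either would be a guess.  Alaska is likewise an override on the
# United States.  Patterns are case-insensitive regular expressions matched
# against the admin-unit text (the part after the colon in GenBank country
# qualifiers, or the BOLD province/state column).
regions:
  West Siberia:
    countries: []
  Fennoscandia:
    countries: [Finland, Sweden, Norway]
  Canada and Alaska:
    countries: [Canada]
overrides:
  - country: Russia
    admin_pattern: "tyumen|omsk|tomsk|novosibirsk|kemerovo|kurgan|altai|khanty|yugra|yamal"
    region: West Siberia
  - country: Russia
    admin_pattern: "murmansk|karelia|kareliya|leningrad"
    region: Fennoscandia
  - country: USA
    admin_pattern: "alaska"
    region: Canada and Alaska
  - country: United States
    admin_pattern: "alaska"
    region: Canada and Alaska
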