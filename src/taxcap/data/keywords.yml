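# Default article-classification configuration.
#
# Phrases are matched case-insensitively as contiguous substrings of the
# whitespace-normalised title and abstract; entries under abstract_only are
# matched in the abstract only ("nov." keeps its literal trailing period so it
# also hits "sp. nov." and "gen. nov."). The English list is the seed set; the
# other languages carry standard translations and every list is overridable.
keywords_by_language:
  en:
    - taxonomic
    - taxon
    - checklist
    - new species
    - novel species
    - new genus
    - new genera
  bg:
    - таксономичен
    - таксон
    - нов вид
    - нов род
  cs:
    - taxonomický
    - taxon
    - nový druh
    - nový rod
  fr:
    - taxonomique
    - taxon
    - nouvelle espèce
    - nouveau genre
  de:
    - taxonomisch
    - taxon
    - neue Art
    - neue Gattung
  hu:
    - taxonómiai
    - taxon
    - új faj
    - új nemzetség
  it:
    - tassonomico
    - taxon
    - nuova specie
    - nuovo genere
  pl:
    - taksonomiczny
    - takson
    - nowy gatunek
    - nowy rodzaj
  pt:
    - taxonómico
    - táxon
    - nova espécie
    - novo género
  ro:
    - taxonomic
    - taxon
    - specie nouă
    - gen nou
  ru:
    - таксономический
    - таксон
    - новый вид
    - новый род
  es:
    - taxonómico
    - taxón
    - nueva especie
    - nuevo género
abstract_only_keywords:
  - "nov."
taxonomic_concept_ids:
  - C58642233   # taxonomy
  - C71640776   # taxon
life_sciences_domain_id: "https://openalex.org/domains/1"
window_start: "2014-01-01"
window_end: "2023-12-31"
# Europe: European Political Community members plus Vatican City and European
# dependencies/territories. Editable.
european_country_codes:
  - "AD"
  - "AL"
  - "AM"
  - "AT"
  - "AX"
  - "AZ"
  - "BA"
  - "BE"
  - "BG"
  - "CH"
  - "CY"
  - "CZ"
  - "DE"
  - "DK"
  - "EE"
  - "ES"
  - "FI"
  - "FO"
  - "FR"
  - "GB"
  - "GE"
  - "GG"
  - "GI"
  - "GR"
  - "HR"
  - "HU"
  - "IE"
  - "IM"
  - "IS"
  - "IT"
  - "JE"
  - "LI"
  - "LT"
  - "LU"
  - "LV"
  - "MC"
  - "MD"
  - "ME"
  - "MK"
  - "MT"
  - "NL"
  - "NO"
  - "PL"
  - "PT"
  - "RO"
  - "RS"
  - "SE"
  - "SI"
  - "SJ"
  - "SK"
  - "SM"
  - "TR"
  - "UA"
  - "VA"
  - "XK"
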