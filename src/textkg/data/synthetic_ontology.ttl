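@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix onto: <http://example.org/onto/thesaurus#> .
@prefix p: <http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#> .

onto:C1000 a owl:Class ; rdfs:label "Development" ; p:UMLS_CUI "C0243107" .
onto:C1001 a owl:Class ; rdfs:label "Cognitive Impairment" ; p:UMLS_CUI "C0338656" .
onto:C1002 a owl:Class ; rdfs:label "Prevalence" ; p:UMLS_CUI "C0033105" .
onto:C1003 a owl:Class ; rdfs:label "Study" ; p:UMLS_CUI "C0557651" .
onto:C1004 a owl:Class ; rdfs:label "Population Group" ; p:UMLS_CUI "C0032659" .
onto:C1005 a owl:Class ; rdfs:label "Risk Factor" ; p:UMLS_CUI "C0035648" .
onto:C1006 a owl:Class ; rdfs:label "Attention" ; p:UMLS_CUI "C0004268" .
onto:C1007 a owl:Class ; rdfs:label "Developmental Process" ; p:UMLS_CUI "C0243107" .
onto:C1008 a owl:Class ; rdfs:label "Dementia" ; p:UMLS_CUI "C0011265" .
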