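<?xml version="1.0" encoding="utf-8"?>
<rdf:RDF
  xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"
  xmlns:owl="http://www.w3.org/2002/07/owl#"
  xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
>
  <owl:Ontology rdf:about="https://w3id.org/metasheet/onto#">
    <rdfs:comment>Synthetic stand-in ontology for the Metadatasheet standard: classes and properties needed to export sheets and measured units as OWL individuals. Constructed for this package's test and export machinery; not the published ontology.</rdfs:comment>
  </owl:Ontology>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#cell_type">
    <rdfs:label>cell type</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#library_prep_kit">
    <rdfs:label>library prep kit</rdfs:label>
  </owl:DatatypeProperty>
  <owl:ObjectProperty rdf:about="https://w3id.org/metasheet/onto#partOfSheet">
    <rdfs:label>part of sheet</rdfs:label>
  </owl:ObjectProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#tissue">
    <rdfs:label>tissue</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#experimental_system">
    <rdfs:label>experimental system</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#availability">
    <rdfs:label>availability</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#line">
    <rdfs:label>line</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#treatment">
    <rdfs:label>treatment</rdfs:label>
  </owl:DatatypeProperty>
  <owl:Class rdf:about="https://w3id.org/metasheet/onto#Subsample">
    <rdfs:label>Subsample</rdfs:label>
  </owl:Class>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#instance">
    <rdfs:label>instance</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#measurement_type">
    <rdfs:label>measurement type</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#sequencing_platform">
    <rdfs:label>sequencing platform</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#protocol">
    <rdfs:label>protocol</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#sex">
    <rdfs:label>sex</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#age">
    <rdfs:label>age</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#used_facility">
    <rdfs:label>used facility</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#diet">
    <rdfs:label>diet</rdfs:label>
  </owl:DatatypeProperty>
  <owl:ObjectProperty rdf:about="https://w3id.org/metasheet/onto#hasMeasuredUnit">
    <rdfs:label>has measured unit</rdfs:label>
  </owl:ObjectProperty>
  <owl:Class rdf:about="https://w3id.org/metasheet/onto#Metadatasheet">
    <rdfs:label>Metadatasheet</rdfs:label>
  </owl:Class>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#replicate">
    <rdfs:label>replicate</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#comment">
    <rdfs:label>comment</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#temperature">
    <rdfs:label>temperature</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#affiliation">
    <rdfs:label>affiliation</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#personal_ID">
    <rdfs:label>personal_ID</rdfs:label>
  </owl:DatatypeProperty>
  <owl:ObjectProperty rdf:about="https://w3id.org/metasheet/onto#ontologyTerm">
    <rdfs:label>ontology term</rdfs:label>
  </owl:ObjectProperty>
  <owl:AnnotationProperty rdf:about="https://w3id.org/metasheet/onto#attribute">
    <rdfs:label>attribute</rdfs:label>
  </owl:AnnotationProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#filename">
    <rdfs:label>filename</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#other">
    <rdfs:label>other</rdfs:label>
  </owl:DatatypeProperty>
  <owl:Class rdf:about="https://w3id.org/metasheet/onto#MeasuredUnit">
    <rdfs:label>MeasuredUnit</rdfs:label>
  </owl:Class>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#final_group">
    <rdfs:label>final_group</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#project_title">
    <rdfs:label>project title</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#genotype">
    <rdfs:label>genotype</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#email">
    <rdfs:label>email</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#linkage_mode">
    <rdfs:label>linkage mode</rdfs:label>
  </owl:DatatypeProperty>
  <owl:DatatypeProperty rdf:about="https://w3id.org/metasheet/onto#name">
    <rdfs:label>name</rdfs:label>
  </owl:DatatypeProperty>
</rdf:RDF>
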