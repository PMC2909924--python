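<?xml version="1.0" encoding="UTF-8"?>
<!--
  XML Schema for the QSAR-ML dataset exchange format as realized by this
  package. A document is a complete, reproducible QSAR dataset setup:
  metadata, checksummed structure resources with per-record InChIs,
  ontology-referenced descriptors bound to versioned provider
  implementations, measured responses, and calculated descriptor values.

  Cross-references (idref attributes) are plain tokens here; referential
  integrity is checked by the data model after parsing, the schema only
  enforces syntax, element structure and order.
-->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           xmlns:q="https://qsar-ml.dev/schema/1.0"
           targetNamespace="https://qsar-ml.dev/schema/1.0"
           elementFormDefault="qualified"
           attributeFormDefault="unqualified">

  <xs:simpleType name="hexDigest">
    <xs:restriction base="xs:string">
      <xs:pattern value="[0-9a-f]+"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="checksumAlgorithm">
    <xs:restriction base="xs:string">
      <xs:enumeration value="SHA-256"/>
      <xs:enumeration value="SHA-1"/>
      <xs:enumeration value="MD5"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="resourceFormat">
    <xs:restriction base="xs:string">
      <xs:enumeration value="SDF"/>
      <xs:enumeration value="SMILES"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="parameterKind">
    <xs:restriction base="xs:string">
      <xs:enumeration value="string"/>
      <xs:enumeration value="integer"/>
      <xs:enumeration value="decimal"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="standardInchi">
    <xs:restriction base="xs:string">
      <xs:pattern value="InChI=1S/.*"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:complexType name="referenceType">
    <xs:attribute name="title" type="xs:string" default=""/>
    <xs:attribute name="identifier" type="xs:string" default=""/>
  </xs:complexType>

  <xs:complexType name="metadataType">
    <xs:sequence>
      <xs:element name="author" type="xs:string" minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="license" type="xs:string" minOccurs="0"/>
      <xs:element name="description" type="xs:string" minOccurs="0"/>
      <xs:element name="reference" type="q:referenceType" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="resourceType">
    <xs:attribute name="id" type="xs:string" use="required"/>
    <xs:attribute name="location" type="xs:string" use="required"/>
    <xs:attribute name="checksum" type="q:hexDigest" use="required"/>
    <xs:attribute name="checksumAlgorithm" type="q:checksumAlgorithm" use="required"/>
    <xs:attribute name="format" type="q:resourceFormat" use="required"/>
  </xs:complexType>

  <xs:complexType name="structureType">
    <xs:attribute name="id" type="xs:string" use="required"/>
    <xs:attribute name="resourceRef" type="xs:string" use="required"/>
    <xs:attribute name="resourceIndex" type="xs:nonNegativeInteger" use="required"/>
    <xs:attribute name="inchi" type="q:standardInchi" use="required"/>
  </xs:complexType>

  <xs:complexType name="structureListType">
    <xs:sequence>
      <xs:element name="resource" type="q:resourceType" minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="structure" type="q:structureType" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="descriptorProviderType">
    <xs:attribute name="id" type="xs:string" use="required"/>
    <xs:attribute name="name" type="xs:string" use="required"/>
    <xs:attribute name="version" type="xs:string" use="required"/>
    <xs:attribute name="vendor" type="xs:string" default=""/>
  </xs:complexType>

  <xs:complexType name="parameterType">
    <xs:attribute name="key" type="xs:string" use="required"/>
    <xs:attribute name="kind" type="q:parameterKind" use="required"/>
    <xs:attribute name="value" type="xs:string" use="required"/>
  </xs:complexType>

  <xs:complexType name="descriptorType">
    <xs:sequence>
      <xs:element name="parameter" type="q:parameterType" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:string" use="required"/>
    <xs:attribute name="ontologyRef" type="xs:string" use="required"/>
    <xs:attribute name="providerRef" type="xs:string" use="required"/>
  </xs:complexType>

  <xs:complexType name="descriptorListType">
    <xs:sequence>
      <xs:element name="descriptorProvider" type="q:descriptorProviderType"
                  minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="descriptor" type="q:descriptorType"
                  minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="responseUnitType">
    <xs:attribute name="id" type="xs:string" use="required"/>
    <xs:attribute name="name" type="xs:string" use="required"/>
    <xs:attribute name="definition" type="xs:string" default=""/>
  </xs:complexType>

  <xs:complexType name="responseType">
    <xs:attribute name="structureRef" type="xs:string" use="required"/>
    <xs:attribute name="unitRef" type="xs:string" use="required"/>
    <xs:attribute name="value" type="xs:double" use="required"/>
  </xs:complexType>

  <xs:complexType name="responseListType">
    <xs:sequence>
      <xs:element name="responseUnit" type="q:responseUnitType"
                  minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="response" type="q:responseType"
                  minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="descriptorValueType">
    <xs:simpleContent>
      <xs:extension base="xs:string">
        <xs:attribute name="label" type="xs:string" use="required"/>
        <xs:attribute name="missing" type="xs:boolean" default="false"/>
      </xs:extension>
    </xs:simpleContent>
  </xs:complexType>

  <xs:complexType name="descriptorResultType">
    <xs:sequence>
      <xs:element name="value" type="q:descriptorValueType"
                  minOccurs="1" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="descriptorRef" type="xs:string" use="required"/>
    <xs:attribute name="structureRef" type="xs:string" use="required"/>
  </xs:complexType>

  <xs:complexType name="descriptorResultListType">
    <xs:sequence>
      <xs:element name="descriptorResult" type="q:descriptorResultType"
                  minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:element name="qsarml">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="metadata" type="q:metadataType"/>
        <xs:element name="structureList" type="q:structureListType"/>
        <xs:element name="descriptorList" type="q:descriptorListType"/>
        <xs:element name="responseList" type="q:responseListType"/>
        <xs:element name="descriptorResultList" type="q:descriptorResultListType"/>
      </xs:sequence>
      <xs:attribute name="version" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
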