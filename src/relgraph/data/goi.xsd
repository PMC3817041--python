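<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">
  <xs:simpleType name="rgbTriple">
    <xs:restriction base="xs:string">
      <xs:pattern value="\d{1,3},\d{1,3},\d{1,3}"/>
    </xs:restriction>
  </xs:simpleType>
  <xs:simpleType name="unitCoord">
    <xs:restriction base="xs:double">
      <xs:minInclusive value="0.0"/>
      <xs:maxInclusive value="1.0"/>
    </xs:restriction>
  </xs:simpleType>
  <xs:element name="goi">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="node" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:attribute name="id" type="xs:string" use="required"/>
            <xs:attribute name="label" type="xs:string" use="required"/>
            <xs:attribute name="category" type="xs:string" use="required"/>
            <xs:attribute name="colour" type="rgbTriple" use="required"/>
            <xs:attribute name="x" type="unitCoord" use="required"/>
            <xs:attribute name="y" type="unitCoord" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="edge" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="url" type="xs:string" minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
            <xs:attribute name="source" type="xs:string" use="required"/>
            <xs:attribute name="target" type="xs:string" use="required"/>
            <xs:attribute name="weight" type="xs:nonNegativeInteger" use="required"/>
            <xs:attribute name="sign" type="xs:string" use="required"/>
            <xs:attribute name="colour" type="rgbTriple" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="level" type="xs:nonNegativeInteger" use="required"/>
      <xs:attribute name="centre" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
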