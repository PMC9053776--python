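<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">

  <xs:simpleType name="positiveDouble">
    <xs:restriction base="xs:double">
      <xs:minExclusive value="0"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="unitInterval">
    <xs:restriction base="xs:double">
      <xs:minInclusive value="0"/>
      <xs:maxInclusive value="1"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="compositionToken">
    <xs:restriction base="xs:string"/>
  </xs:simpleType>

  <xs:simpleType name="lobeToken">
    <xs:restriction base="xs:string">
      <xs:enumeration value="RUL"/>
      <xs:enumeration value="RML"/>
      <xs:enumeration value="RLL"/>
      <xs:enumeration value="LUL"/>
      <xs:enumeration value="LLL"/>
      <xs:enumeration value="lingula"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="lateralityToken">
    <xs:restriction base="xs:string">
      <xs:enumeration value="left"/>
      <xs:enumeration value="right"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="sourceToken">
    <xs:restriction base="xs:string">
      <xs:enumeration value="reader"/>
      <xs:enumeration value="vendor"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="unitsToken">
    <xs:restriction base="xs:string">
      <xs:enumeration value="mm"/>
      <xs:enumeration value="index"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="annotation-file">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="header">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="study-id" type="xs:string"/>
              <xs:element name="source">
                <xs:complexType>
                  <xs:attribute name="type" type="sourceToken" use="required"/>
                  <xs:attribute name="id" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
              <xs:element name="pixel-spacing" minOccurs="0">
                <xs:complexType>
                  <xs:attribute name="x-mm" type="positiveDouble" use="required"/>
                  <xs:attribute name="y-mm" type="positiveDouble" use="required"/>
                </xs:complexType>
              </xs:element>
              <xs:element name="slice-spacing" minOccurs="0">
                <xs:complexType>
                  <xs:attribute name="mm" type="positiveDouble" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="nodules">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="nodule" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="series-number" type="xs:integer" minOccurs="0"/>
                    <xs:element name="slice-number" type="xs:integer" minOccurs="0"/>
                    <xs:element name="center">
                      <xs:complexType>
                        <xs:attribute name="x" type="xs:double" use="required"/>
                        <xs:attribute name="y" type="xs:double" use="required"/>
                        <xs:attribute name="z" type="xs:double" use="required"/>
                        <xs:attribute name="units" type="unitsToken" default="mm"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="axes" minOccurs="0">
                      <xs:complexType>
                        <xs:attribute name="long-mm" type="positiveDouble" use="required"/>
                        <xs:attribute name="short-mm" type="positiveDouble" use="required"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="solid-component" minOccurs="0">
                      <xs:complexType>
                        <xs:attribute name="long-mm" type="positiveDouble" use="required"/>
                        <xs:attribute name="short-mm" type="positiveDouble" use="required"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="composition" type="compositionToken" minOccurs="0"/>
                    <xs:element name="location" minOccurs="0">
                      <xs:complexType>
                        <xs:attribute name="lobe" type="lobeToken" use="required"/>
                        <xs:attribute name="laterality" type="lateralityToken" use="required"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="spiculation" type="xs:boolean" minOccurs="0"/>
                    <xs:element name="calcification" minOccurs="0">
                      <xs:complexType>
                        <xs:attribute name="diffuse" type="xs:boolean" use="required"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="confidence" type="unitInterval" minOccurs="0"/>
                    <xs:element name="extensions" minOccurs="0">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:any processContents="skip" minOccurs="0" maxOccurs="unbounded"/>
                        </xs:sequence>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                  <xs:attribute name="id" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="schema-version" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
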