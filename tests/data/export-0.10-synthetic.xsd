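<?xml version="1.0" encoding="UTF-8"?>
<!--
  SYNTHETIC reconstruction of the MediaWiki export XML schema,
  namespace version 0.10, written from the documented structure of
  MediaWiki page dumps for use as an offline validation oracle in the
  test suite.  It mirrors the element names, ordering and optionality
  of the published export-0.10 schema for the subset of the format a
  page-import document uses (siteinfo, page, revision, contributor,
  text); it is not a copy of the published file.
-->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           xmlns:mw="http://www.mediawiki.org/xml/export-0.10/"
           targetNamespace="http://www.mediawiki.org/xml/export-0.10/"
           elementFormDefault="qualified">

  <xs:element name="mediawiki" type="mw:MediaWikiType"/>

  <xs:complexType name="MediaWikiType">
    <xs:sequence>
      <xs:element name="siteinfo" type="mw:SiteInfoType" minOccurs="0"/>
      <xs:element name="page" type="mw:PageType" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="version" type="xs:string" use="required"/>
    <xs:anyAttribute processContents="skip"/>
  </xs:complexType>

  <xs:complexType name="SiteInfoType">
    <xs:sequence>
      <xs:element name="sitename" type="xs:string" minOccurs="0"/>
      <xs:element name="dbname" type="xs:string" minOccurs="0"/>
      <xs:element name="base" type="xs:anyURI" minOccurs="0"/>
      <xs:element name="generator" type="xs:string" minOccurs="0"/>
      <xs:element name="case" type="xs:string" minOccurs="0"/>
      <xs:element name="namespaces" type="mw:NamespacesType" minOccurs="0"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="NamespacesType">
    <xs:sequence>
      <xs:element name="namespace" minOccurs="0" maxOccurs="unbounded">
        <xs:complexType>
          <xs:simpleContent>
            <xs:extension base="xs:string">
              <xs:attribute name="key" type="xs:integer"/>
              <xs:attribute name="case" type="xs:string"/>
            </xs:extension>
          </xs:simpleContent>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="PageType">
    <xs:sequence>
      <xs:element name="title" type="xs:string"/>
      <xs:element name="ns" type="xs:nonNegativeInteger"/>
      <xs:element name="id" type="xs:positiveInteger" minOccurs="0"/>
      <xs:element name="redirect" minOccurs="0">
        <xs:complexType>
          <xs:attribute name="title" type="xs:string"/>
        </xs:complexType>
      </xs:element>
      <xs:element name="restrictions" type="xs:string" minOccurs="0"/>
      <xs:element name="revision" type="mw:RevisionType" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="RevisionType">
    <xs:sequence>
      <xs:element name="id" type="xs:positiveInteger" minOccurs="0"/>
      <xs:element name="parentid" type="xs:positiveInteger" minOccurs="0"/>
      <xs:element name="timestamp" type="xs:dateTime"/>
      <xs:element name="contributor" type="mw:ContributorType"/>
      <xs:element name="minor" minOccurs="0">
        <xs:complexType/>
      </xs:element>
      <xs:element name="comment" type="xs:string" minOccurs="0"/>
      <xs:element name="model" type="xs:string"/>
      <xs:element name="format" type="xs:string"/>
      <xs:element name="text" type="mw:TextType"/>
      <xs:element name="sha1" type="xs:string" minOccurs="0"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="ContributorType">
    <xs:sequence>
      <xs:element name="username" type="xs:string" minOccurs="0"/>
      <xs:element name="id" type="xs:positiveInteger" minOccurs="0"/>
      <xs:element name="ip" type="xs:string" minOccurs="0"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="TextType">
    <xs:simpleContent>
      <xs:extension base="xs:string">
        <xs:anyAttribute processContents="skip"/>
      </xs:extension>
    </xs:simpleContent>
  </xs:complexType>

</xs:schema>
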