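<?xml version="1.0" encoding="UTF-8"?>
<!-- Pinned XML dialect for the Level-1 study manifest (study_description.xml).
     Element names are lowerCamelCase; optional fields are present-but-empty. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">

  <xs:simpleType name="versionText">
    <xs:restriction base="xs:string">
      <xs:pattern value="|[0-9]+(\.[0-9]+)*"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="numberOrEmpty">
    <xs:restriction base="xs:string">
      <xs:pattern value="|-?[0-9]+(\.[0-9]+)?([eE][+-]?[0-9]+)?"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="integerText">
    <xs:restriction base="xs:string">
      <xs:pattern value="-?[0-9]+"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:complexType name="labelListType">
    <xs:sequence>
      <xs:element name="channelLabel" type="xs:string" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="modalityType">
    <xs:sequence>
      <xs:element name="type" type="xs:string"/>
      <xs:element name="startChannel" type="integerText"/>
      <xs:element name="endChannel" type="integerText"/>
      <xs:element name="samplingRate" type="numberOrEmpty"/>
      <xs:element name="channelLabels" type="labelListType"/>
      <xs:element name="nonScalpChannelLabels" type="labelListType"/>
      <xs:element name="channelLocationType" type="xs:string"/>
      <xs:element name="referenceLabel" type="xs:string"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="subjectType">
    <xs:sequence>
      <xs:element name="labId" type="xs:string"/>
      <xs:element name="group" type="xs:string"/>
      <xs:element name="gender" type="xs:string"/>
      <xs:element name="age" type="numberOrEmpty"/>
      <xs:element name="hand" type="xs:string"/>
      <xs:element name="height" type="numberOrEmpty"/>
      <xs:element name="weight" type="numberOrEmpty"/>
      <xs:element name="medication" type="xs:string"/>
      <xs:element name="channelLocationFile" type="xs:string"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="dataRecordingType">
    <xs:sequence>
      <xs:element name="uuid" type="xs:string"/>
      <xs:element name="originalFileNameAndPath" type="xs:string"/>
      <xs:element name="essFilename" type="xs:string"/>
      <xs:element name="eventInstanceFilename" type="xs:string"/>
      <xs:element name="recordingParameterSetId" type="xs:string"/>
      <xs:element name="startDateTime" type="xs:string"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="sessionType">
    <xs:sequence>
      <xs:element name="number" type="integerText"/>
      <xs:element name="taskLabel" type="xs:string"/>
      <xs:element name="notes" type="xs:string"/>
      <xs:element name="subjects">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="subject" type="subjectType" minOccurs="0" maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element name="dataRecordings">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="dataRecording" type="dataRecordingType" minOccurs="0" maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
  </xs:complexType>

  <xs:element name="studyLevel1">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="title" type="xs:string"/>
        <xs:element name="description" type="xs:string"/>
        <xs:element name="essVersion" type="versionText"/>
        <xs:element name="studyUuid" type="xs:string"/>
        <xs:element name="publications" type="xs:string"/>
        <xs:element name="pointOfContact" type="xs:string"/>
        <xs:element name="license" type="xs:string"/>
        <xs:element name="tasks">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="task" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="taskLabel" type="xs:string"/>
                    <xs:element name="description" type="xs:string"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="recordingParameterSets">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="recordingParameterSet" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="recordingParameterSetId" type="xs:string"/>
                    <xs:element name="modality" type="modalityType" minOccurs="0" maxOccurs="unbounded"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="eventCodeMappings">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="eventCodeMapping" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="taskLabel" type="xs:string"/>
                    <xs:element name="code" type="xs:string"/>
                    <xs:element name="category" type="xs:string"/>
                    <xs:element name="hedString" type="xs:string"/>
                    <xs:element name="description" type="xs:string"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="sessions">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="session" type="sessionType" minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:any processContents="skip" minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>
</xs:schema>
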