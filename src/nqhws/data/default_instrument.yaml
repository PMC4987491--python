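# Canonical National Quality Health Website Survey instrument:
# Healthy People 2020 objectives HC/HIT-8.1 (information reliability;
# 6 criteria of yes/no disclosure elements) and HC/HIT-8.2 (usability;
# 19 established principles across 59 task-based measures rated 1-4).
#
# The published survey's 59 individual measure texts are not reproduced;
# each principle declares n_measures and placeholder measures are
# generated. Scoring is allocation-agnostic.
version: "HP2020-NQHWS-1.0"
reliability_benchmark_min: 3
usability_benchmark_min: 10
criteria:
  - criterion_id: Identity
    elements:
      - element_id: org-name
        text: Name of person or organization responsible for website
      - element_id: street-address
        text: Street address for person or organization responsible for website
      - element_id: funding-source
        text: Identified source of funding for website
  - criterion_id: Purpose
    elements:
      - element_id: purpose-statement
        text: Statement of purpose or mission for website
      - element_id: uses-limitations
        text: Uses and limitations of services provided
      - element_id: commercial-association
        text: Association with commercial products or services
  - criterion_id: ContentDevelopment
    elements:
      - element_id: advertising-differentiation
        text: Differentiation of advertising from nonadvertising content
        conditional: true
      - element_id: editorial-policy
        text: Medical, editorial, or quality review practices or policies
      - element_id: authorship
        text: Authorship of health content (per page of health content)
        page_scoped: true
  - criterion_id: Privacy
    elements:
      - element_id: privacy-policy
        text: Privacy policy
      - element_id: personal-info-protection
        text: How personal information is protected
  - criterion_id: UserFeedback
    elements:
      - element_id: feedback-mechanism
        text: Feedback form or mechanism
      - element_id: user-info-use
        text: How information from users is used
        required: false
  - criterion_id: ContentUpdating
    elements:
      - element_id: date-created
        text: Date content created (per page of health content)
        page_scoped: true
      - element_id: date-reviewed
        text: Date content reviewed, updated, modified, or revised (per page of health content)
        page_scoped: true
      - element_id: copyright-date
        text: Copyright date
        required: false
principles:
  - principle_id: 1
    category: SiteDesign
    name: Use conventional interaction elements
    n_measures: 4
  - principle_id: 2
    category: SiteDesign
    name: Make it obvious what is clickable and what is not
    n_measures: 3
  - principle_id: 3
    category: SiteDesign
    name: Minimize vertical scrolling
    n_measures: 3
  - principle_id: 4
    category: SiteDesign
    name: Ensure that the Back button behaves predictably
    n_measures: 3
  - principle_id: 5
    category: SiteDesign
    name: Provide clear feedback signals for actions
    n_measures: 3
  - principle_id: 6
    category: SiteDesign
    name: Ensure site is accessible for users with disabilities and uses elements of 508 compliance
    n_measures: 3
  - principle_id: 7
    category: SiteDesign
    name: Provide a simplified user experience
    n_measures: 3
  - principle_id: 8
    category: SiteDesign
    name: Incorporate multimedia
    n_measures: 3
  - principle_id: 9
    category: SiteDesign
    name: Offer a functional home page
    n_measures: 3
  - principle_id: 10
    category: InformationArchitecture
    name: Present a clear visual hierarchy
    n_measures: 3
  - principle_id: 11
    category: InformationArchitecture
    name: Provide easy search functionality
    n_measures: 4
  - principle_id: 12
    category: InformationArchitecture
    name: Clearly label content categories
    n_measures: 3
  - principle_id: 13
    category: InformationArchitecture
    name: Make pages easy to skim or scan
    n_measures: 3
  - principle_id: 14
    category: InformationArchitecture
    name: Make elements on the page easy to read
    n_measures: 3
  - principle_id: 15
    category: InformationArchitecture
    name: Visually group related topics
    n_measures: 3
  - principle_id: 16
    category: InformationArchitecture
    name: Make sure text and background colors contrast
    n_measures: 3
  - principle_id: 17
    category: ContentDesign
    name: Focus the writing on audience and purpose
    n_measures: 3
  - principle_id: 18
    category: ContentDesign
    name: Use the users' language; minimize jargon and technical terms
    n_measures: 3
  - principle_id: 19
    category: ContentDesign
    name: Allow for interaction with the content
    n_measures: 3
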